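import numpy as np
import pandas as pd
import pytest

from rtwalk.cohort import (
    MoveRecord,
    filter_middle_game,
    fit_per_instant,
    fit_players,
    quintile_analysis,
    similarity_rank_correlation,
    validate_records,
)
from rtwalk.dist import bin_rt
from rtwalk.errors import (
    InsufficientPopulationError,
    InvalidParameterError,
)
from rtwalk.fitting import FitSpace, fit_model
from rtwalk.grid import ObstaclesParams
from rtwalk.simulate import batch_fpt
from rtwalk.synth import AffineMap, CohortConfig, gen_cohort

SMALL = dict(
    sims_per_eval=4000,
    coarse_sims=2000,
    coarse_shape_points=8,
    refine_top_k=2,
    n_starts=2,
    nm_max_iter=12,
)


def make_records(remaining, total=300.0, rt=1.0, rating=1500.0):
    return pd.DataFrame(
        {
            "player_id": "p0",
            "rating": rating,
            "game_id": "g0",
            "total_time_s": total,
            "remaining_time_s": remaining,
            "rt_s": rt,
        }
    )


class TestMoveRecord:
    def test_valid(self):
        MoveRecord("p", 1500.0, "g", 300.0, 100.0, 2.0)

    def test_invariant(self):
        with pytest.raises(InvalidParameterError):
            MoveRecord("p", 1500.0, "g", 300.0, 100.0, 200.0)
        with pytest.raises(InvalidParameterError):
            MoveRecord("p", 1500.0, "g", 300.0, 400.0, 2.0)


class TestMiddleGame:
    def test_fraction_095_dropped(self):
        assert len(filter_middle_game(make_records([285.0]))) == 0

    def test_fraction_05_kept(self):
        assert len(filter_middle_game(make_records([150.0]))) == 1

    def test_300s_window_is_30_to_270(self):
        df = make_records([270.0, 270.1, 30.0, 29.9])
        kept = filter_middle_game(df)["remaining_time_s"].tolist()
        assert kept == [270.0, 30.0]

    def test_idempotent(self):
        df = make_records(list(np.linspace(5, 295, 40)))
        once = filter_middle_game(df)
        twice = filter_middle_game(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_validate_missing_column(self):
        with pytest.raises(InvalidParameterError):
            validate_records(pd.DataFrame({"rt_s": [1.0]}))


class TestQuintiles:
    def _corpus(self, seed=0, slopes=(0.25, -3.0)):
        cfg = CohortConfig(
            n_players=12,
            games_per_player=8,
            density_map=AffineMap(0.30, slopes[0], (0.2, 0.65)),
            radius_map=AffineMap(6.5, slopes[1], (1.0, 10.0)),
            master_seed=seed,
        )
        table, _ = gen_cohort(cfg)
        return filter_middle_game(table)

    def test_partition_sizes(self):
        mid = self._corpus()
        space = FitSpace.for_model("obstacles", radius_values=(4,), sims_per_eval=500,
                                   coarse_sims=500, coarse_shape_points=3, refine_top_k=1,
                                   n_starts=1, nm_max_iter=3)
        res = quintile_analysis(mid, n_groups=5, space=space, seed=0)
        sizes = [g["n_records"] for g in res.groups]
        assert sum(sizes) == len(mid)
        assert max(sizes) - min(sizes) <= 1

    def test_sign_recovery_default_generator(self):
        mid = self._corpus(seed=3)
        space = FitSpace.for_model("obstacles", **SMALL)
        res = quintile_analysis(mid, space=space, seed=3)
        assert res.correlations["shape"][0] > 0
        assert res.correlations["radius_R"][0] < 0

    def test_null_generator_mostly_insignificant(self):
        # flat parameter maps: expect ~5% false positives at alpha = 0.05
        significant = 0
        for seed in range(6):
            mid = self._corpus(seed=100 + seed, slopes=(0.0, 0.0))
            space = FitSpace.for_model(
                "obstacles", radius_values=(5, 6, 7, 8), **SMALL
            )
            res = quintile_analysis(mid, space=space, seed=seed)
            for key in ("shape", "radius_R"):
                corr = res.correlations[key]
                if corr is not None and corr[1] < 0.05:
                    significant += 1
        assert significant <= 3

    def test_degenerate_ratings_reported_none(self):
        df = make_records(list(np.linspace(40, 260, 200)), rt=1.0)
        df["rt_s"] = np.random.default_rng(0).uniform(0.5, 3.0, len(df))
        space = FitSpace.for_model("obstacles", radius_values=(3,), sims_per_eval=500,
                                   coarse_sims=500, coarse_shape_points=3, refine_top_k=1,
                                   n_starts=1, nm_max_iter=3)
        res = quintile_analysis(df, n_groups=2, space=space, seed=0)
        assert res.correlations["shape"] is None

    def test_too_few_records(self):
        with pytest.raises(InsufficientPopulationError):
            quintile_analysis(make_records([150.0]), n_groups=5)


class TestSimilarity:
    def _hists(self, n_players, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for i in range(n_players):
            rt = rng.gamma(2.0 + i, 1.0 + 0.3 * i, size=2000)
            out[f"p{i}"] = bin_rt(rt, 0.1, 60.0)
        return out

    def test_identical_fits_give_perfect_correlation(self):
        real = self._hists(6)
        res = similarity_rank_correlation(real, real)
        assert all(rho == pytest.approx(1.0) for rho, _ in res.values())

    def test_random_fits_average_to_zero(self):
        # structureless stand-ins: random histograms unrelated to any player
        real = self._hists(6)
        edges = next(iter(real.values())).bin_edges
        rng = np.random.default_rng(99)
        rhos = []
        for _ in range(100):
            fake = {}
            for pid in real:
                probs = rng.dirichlet(np.full(edges.size - 1, 0.05))
                from rtwalk.dist import RTHistogram

                fake[pid] = RTHistogram(edges, probs / probs.sum())
            res = similarity_rank_correlation(real, fake)
            rhos.extend(rho for rho, _ in res.values())
        assert abs(np.mean(rhos)) < 0.1

    def test_needs_three_players(self):
        real = self._hists(2)
        with pytest.raises(InsufficientPopulationError):
            similarity_rank_correlation(real, real)

    def test_key_mismatch(self):
        real = self._hists(4)
        fake = {k: v for k, v in list(real.items())[:3]}
        with pytest.raises(InvalidParameterError):
            similarity_rank_correlation(real, fake)

    def test_separated_cohort_high_correlation(self):
        # well-separated generating parameters, fitted histograms from the
        # generating model itself: orderings should agree strongly
        real, fitted = {}, {}
        for i, (q, dt) in enumerate([(0.25, 40.0), (0.4, 70.0), (0.55, 100.0), (0.3, 130.0)]):
            params = ObstaclesParams(4, q, dt)
            real[f"p{i}"] = bin_rt(batch_fpt("obstacles", params, 20_000, seed=i).rt_s)
            fitted[f"p{i}"] = bin_rt(batch_fpt("obstacles", params, 20_000, seed=100 + i).rt_s)
        res = similarity_rank_correlation(real, fitted)
        assert all(rho > 0.9 for rho, _ in res.values())


class TestFitPlayers:
    def _corpus(self):
        cfg = CohortConfig(n_players=3, games_per_player=6, master_seed=5)
        table, truth = gen_cohort(cfg)
        return table, truth

    def test_min_games_filter(self):
        table, _ = self._corpus()
        out = fit_players(table, min_games=10_000)
        assert out == {}

    def test_fits_each_player_and_obstacles_wins(self):
        table, _ = self._corpus()
        spaces = {
            "obstacles": FitSpace.for_model("obstacles", radius_values=(3, 4, 5, 6, 7), **SMALL),
            "ddm": FitSpace.for_model("ddm", radius_values=(3, 4, 5, 6, 7), **SMALL),
        }
        out = fit_players(
            table[table.player_id == "p0000"],
            min_games=2,
            space=spaces,
            model_kinds=("obstacles", "ddm"),
        )
        assert "p0000" in out
        fits = out["p0000"]["fits"]
        assert fits["obstacles"]["jsd"] < fits["ddm"]["jsd"]

    def test_two_identical_players_agree(self):
        params = ObstaclesParams(4, 0.45, 90.0)
        rows = []
        for i, seed in enumerate((1, 2)):
            rt = batch_fpt("obstacles", params, 4000, seed=seed).rt_s
            rows.append(
                pd.DataFrame(
                    {
                        "player_id": f"p{i}",
                        "rating": 1500.0,
                        "game_id": [f"p{i}-g{j}" for j in range(len(rt))],
                        "total_time_s": 300.0,
                        "remaining_time_s": 150.0,
                        "rt_s": np.clip(rt, 0.01, 150.0),
                    }
                )
            )
        table = pd.concat(rows, ignore_index=True)
        spaces = {"obstacles": FitSpace.for_model("obstacles", radius_values=(3, 4, 5), **SMALL)}
        out = fit_players(table, min_games=100, space=spaces)
        p0 = out["p0"]["fits"]["obstacles"]["result"].params
        p1 = out["p1"]["fits"]["obstacles"]["result"].params
        assert p0.radius_R == p1.radius_R
        assert p0.obstacle_density_q == pytest.approx(p1.obstacle_density_q, abs=0.08)
        assert p0.dt_ms == pytest.approx(p1.dt_ms, abs=10.0)


class TestFitPerInstant:
    def test_single_bin_consistent_with_pool_fit(self):
        cfg = CohortConfig(n_players=4, games_per_player=4, master_seed=9)
        table, _ = gen_cohort(cfg)
        space = FitSpace.for_model("obstacles", radius_values=(4, 5, 6), **SMALL)
        entries = fit_per_instant(
            table, instant_bin_width_s=1000.0, space=space, min_records=10, seed=2
        )
        fitted = [e for e in entries if not e["skipped"]]
        assert len(fitted) == 1
        pool = filter_middle_game(table)
        direct = fit_model("obstacles", bin_rt(pool["rt_s"].to_numpy()), space, seed=2)
        assert fitted[0]["fits"]["obstacles"]["result"].params == direct.params

    def test_undersized_bins_skipped(self):
        df = make_records(list(np.linspace(40, 260, 30)))
        df["rt_s"] = np.random.default_rng(1).uniform(0.5, 3.0, len(df))
        entries = fit_per_instant(df, instant_bin_width_s=10.0, min_records=500)
        assert all(e["skipped"] for e in entries)

    def test_instant_independent_generator(self):
        # homogeneous population: every player shares one parameter triple,
        # so per-instant fits should agree with each other and match medians
        cfg = CohortConfig(
            n_players=6,
            games_per_player=40,
            density_map=AffineMap(0.45, 0.0, (0.2, 0.65)),
            radius_map=AffineMap(4.0, 0.0, (1.0, 10.0)),
            master_seed=11,
        )
        table, _ = gen_cohort(cfg)
        space = FitSpace.for_model(
            "obstacles",
            radius_values=(3, 4, 5),
            sims_per_eval=15_000,
            coarse_sims=4000,
            coarse_shape_points=10,
            refine_top_k=2,
            n_starts=2,
            nm_max_iter=15,
        )
        entries = fit_per_instant(
            table, instant_bin_width_s=120.0, space=space, min_records=2000, seed=4
        )
        fitted = [e for e in entries if not e["skipped"]]
        assert len(fitted) >= 2
        radii = {e["fits"]["obstacles"]["result"].params.radius_R for e in fitted}
        assert radii == {4}
        qs = [e["fits"]["obstacles"]["result"].params.obstacle_density_q for e in fitted]
        assert max(qs) - min(qs) < 0.1
        gaps = [
            abs(e["empirical_median_s"] - e["fits"]["obstacles"]["model_median_s"])
            for e in fitted
        ]
        assert np.mean(gaps) < 0.1  # within one RT bin width
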