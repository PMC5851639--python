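"""Population-level analyses on move-record tables.

A move record is one timed decision: who made it, their skill rating, in
which game, and how much clock remained. Analyses work on pandas
DataFrames with the canonical columns in :data:`REQUIRED_COLUMNS`;
:class:`MoveRecord` is the single-row view.

The analyzed regime is the *middle game*: moves made while the remaining
fraction of the time budget lies in [0.1, 0.9] (for a 300 s budget,
remaining clock between 270 s and 30 s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dist import DEFAULT_BIN_WIDTH_S, DEFAULT_CAP_S, RTHistogram, bin_rt, jsd
from .errors import InsufficientPopulationError, InvalidParameterError
from .fitting import FitResult, FitSpace, fit_model

__all__ = [
    "MoveRecord",
    "CohortResult",
    "REQUIRED_COLUMNS",
    "validate_records",
    "filter_middle_game",
    "fit_per_instant",
    "fit_players",
    "similarity_rank_correlation",
    "quintile_analysis",
]

REQUIRED_COLUMNS = ["player_id", "rating", "game_id", "total_time_s", "remaining_time_s", "rt_s"]

MIDDLE_GAME_LO = 0.1
MIDDLE_GAME_HI = 0.9


@dataclass(frozen=True)
class MoveRecord:
    """One observed decision with its clock context."""

    player_id: str
    rating: float
    game_id: str
    total_time_s: float
    remaining_time_s: float
    rt_s: float

    def __post_init__(self):
        if not 0 < self.rt_s <= self.remaining_time_s <= self.total_time_s:
            raise InvalidParameterError(
                f"need 0 < rt_s <= remaining_time_s <= total_time_s, got "
                f"rt={self.rt_s}, remaining={self.remaining_time_s}, total={self.total_time_s}"
            )


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise InvalidParameterError(f"records table is missing columns {missing}")
    bad = ~(
        (records["rt_s"] > 0)
        & (records["rt_s"] <= records["remaining_time_s"])
        & (records["remaining_time_s"] <= records["total_time_s"])
    )
    if bad.any():
        raise InvalidParameterError(
            f"{int(bad.sum())} records violate 0 < rt_s <= remaining_time_s <= total_time_s"
        )
    return records


def filter_middle_game(records: pd.DataFrame) -> pd.DataFrame:
    """Keep moves with remaining-time fraction in [0.1, 0.9] (closed).

    Idempotent: filtering twice equals filtering once.
    """
    frac = records["remaining_time_s"] / records["total_time_s"]
    return records.loc[(frac >= MIDDLE_GAME_LO) & (frac <= MIDDLE_GAME_HI)]


def _space_for(space, kind: str) -> FitSpace:
    """Resolve a FitSpace, a per-model-kind dict of them, or None."""
    if space is None:
        return FitSpace.for_model(kind)
    if isinstance(space, dict):
        return space.get(kind) or FitSpace.for_model(kind)
    return space


def fit_per_instant(
    records: pd.DataFrame,
    instant_bin_width_s: float,
    space: FitSpace | dict | None = None,
    model_kinds=("obstacles",),
    min_records: int = 500,
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    cap: float = DEFAULT_CAP_S,
    seed: int = 0,
) -> list[dict]:
    """Independent fit in each remaining-time bin of the middle game.

    Bins with fewer than ``min_records`` moves are skipped (reported with
    ``"skipped": True``). Each entry carries the empirical RT median of
    the bin and the median of every fitted model's distribution.
    """
    if instant_bin_width_s <= 0:
        raise InvalidParameterError("instant_bin_width_s must be > 0")
    mid = filter_middle_game(validate_records(records))
    edges_lo = np.floor(mid["remaining_time_s"].min() / instant_bin_width_s) * instant_bin_width_s
    idx = ((mid["remaining_time_s"] - edges_lo) / instant_bin_width_s).astype(int)
    out = []
    for b, sub in mid.groupby(idx, sort=True):
        center = edges_lo + (b + 0.5) * instant_bin_width_s
        entry: dict = {"remaining_time_center_s": float(center), "n_records": int(len(sub))}
        if len(sub) < min_records:
            entry["skipped"] = True
            out.append(entry)
            continue
        entry["skipped"] = False
        hist = bin_rt(sub["rt_s"].to_numpy(), bin_width, cap)
        entry["empirical_median_s"] = hist.median()
        entry["fits"] = {}
        for kind in model_kinds:
            sp = _space_for(space, kind)
            fit = fit_model(kind, hist, sp, seed=seed)
            model_hist = _model_histogram(kind, fit, sp, hist.bin_edges, seed)
            entry["fits"][kind] = {
                "result": fit,
                "model_median_s": model_hist.median(),
            }
        out.append(entry)
    return out


def _model_histogram(kind, fit: FitResult, space: FitSpace, edges, seed) -> RTHistogram:
    from .fitting import _hist_probs_from_steps, derived_seed
    from .simulate import batch_fpt

    sample = batch_fpt(
        kind,
        fit.params,
        n_sims=space.sims_per_eval,
        seed=derived_seed(seed + 1, kind, fit.params.radius_R, 0.5),
        disorder_mode=space.disorder_mode,
    )
    probs = _hist_probs_from_steps(sample.steps, fit.params.dt_ms, edges)
    return RTHistogram(bin_edges=edges, probabilities=probs, n_samples=sample.steps.size)


def fit_players(
    records: pd.DataFrame,
    min_games: int = 20_000,
    space: FitSpace | dict | None = None,
    model_kinds=("obstacles",),
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    cap: float = DEFAULT_CAP_S,
    seed: int = 0,
) -> dict:
    """One fit per model per player, on the player's middle-game RTs.

    Players with ``min_games`` or fewer distinct games are excluded (the
    reference analysis kept players with more than 20,000 games each).
    """
    mid = filter_middle_game(validate_records(records))
    out: dict = {}
    for pid, sub in mid.groupby("player_id", sort=True):
        if sub["game_id"].nunique() <= min_games:
            continue
        hist = bin_rt(sub["rt_s"].to_numpy(), bin_width, cap)
        entry = {"n_games": int(sub["game_id"].nunique()), "n_moves": int(len(sub)),
                 "rating": float(sub["rating"].mean()), "histogram": hist, "fits": {}}
        for kind in model_kinds:
            sp = _space_for(space, kind)
            fit = fit_model(kind, hist, sp, seed=seed)
            entry["fits"][kind] = {
                "result": fit,
                "model_histogram": _model_histogram(kind, fit, sp, hist.bin_edges, seed),
                "jsd": fit.objective,
            }
        out[pid] = entry
    return out


def similarity_rank_correlation(
    real_hists: dict[str, RTHistogram],
    fitted_hists: dict[str, RTHistogram],
) -> dict[str, tuple[float, float]]:
    """Do model fits preserve who-resembles-whom?

    For each player, every *other* player is scored twice: by the JSD of
    their real histogram to this player's real histogram, and to this
    player's fitted-model histogram. Returns the Spearman rank correlation
    (rho, p) of the two orderings per player; ties get average ranks.
    """
    players = sorted(real_hists)
    if len(players) < 3:
        raise InsufficientPopulationError("similarity ranking needs at least 3 players")
    if sorted(fitted_hists) != players:
        raise InvalidParameterError("real and fitted histogram keys must match")
    out = {}
    for pid in players:
        others = [q for q in players if q != pid]
        d_real = [jsd(real_hists[pid], real_hists[q]) for q in others]
        d_fit = [jsd(fitted_hists[pid], real_hists[q]) for q in others]
        rho, p = stats.spearmanr(d_real, d_fit)
        out[pid] = (float(rho), float(p))
    return out


@dataclass(frozen=True)
class CohortResult:
    """Per-group fits plus parameter-vs-rating correlations."""

    groups: list
    correlations: dict

    def to_dict(self) -> dict:
        return {"groups": self.groups, "correlations": self.correlations}


def quintile_analysis(
    records: pd.DataFrame,
    n_groups: int = 5,
    space: FitSpace | None = None,
    model_kind: str = "obstacles",
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    cap: float = DEFAULT_CAP_S,
    seed: int = 0,
) -> CohortResult:
    """Equal-count rating groups, one fit each, parameter-rating correlations.

    Records are sorted by rating and cut into ``n_groups`` groups with
    sizes differing by at most one record (equal *move* counts, not equal
    player counts). The model is fitted to each group's RT histogram and
    each fitted parameter (density/noise, dt, radius) is correlated with
    the group mean rating (two-sided Pearson). Degenerate ratings make the
    correlation undefined; it is reported as ``None``.
    """
    df = validate_records(records)
    if len(df) < n_groups:
        raise InsufficientPopulationError(f"need at least {n_groups} records")
    order = np.argsort(df["rating"].to_numpy(), kind="stable")
    chunks = np.array_split(order, n_groups)
    groups = []
    for gi, chunk in enumerate(chunks):
        sub = df.iloc[chunk]
        sp = space if space is not None else FitSpace.for_model(model_kind)
        hist = bin_rt(sub["rt_s"].to_numpy(), bin_width, cap)
        fit = fit_model(model_kind, hist, sp, seed=seed)
        p = fit.params
        shape = p.obstacle_density_q if model_kind == "obstacles" else p.epsilon
        groups.append(
            {
                "group": gi,
                "n_records": int(len(sub)),
                "mean_rating": float(sub["rating"].mean()),
                "shape": float(shape),
                "dt_ms": float(p.dt_ms),
                "radius_R": int(p.radius_R),
                "objective_jsd": float(fit.objective),
            }
        )
    ratings = np.array([g["mean_rating"] for g in groups])
    correlations = {}
    for key in ("shape", "dt_ms", "radius_R"):
        vals = np.array([g[key] for g in groups], dtype=float)
        if np.ptp(ratings) == 0 or np.ptp(vals) == 0:
            correlations[key] = None
        else:
            r, p = stats.pearsonr(ratings, vals)
            correlations[key] = (float(r), float(p))
    return CohortResult(groups=groups, correlations=correlations)
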