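"""Synthetic response-time corpora with known ground truth.

Generates desk-scale populations of players whose response times are
drawn from one of the two walker models, with per-player parameters tied
to a skill rating through affine maps. The default maps embed the
expertise structure the cohort analyses look for: obstacle density rising
with rating, boundary radius falling, time-per-step flat.

Ground-truth parameters are returned separately (a sidecar, never written
into the analysis table) so recovery tests stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .grid import DDMParams, ObstaclesParams
from .simulate import batch_fpt

__all__ = ["AffineMap", "CohortConfig", "gen_rt_sample", "gen_cohort"]


@dataclass(frozen=True)
class AffineMap:
    """``value(x) = intercept + slope * x`` on normalized rating x in [0, 1],
    clipped to ``clip``."""

    intercept: float
    slope: float
    clip: tuple[float, float]

    def __call__(self, x: float) -> float:
        lo, hi = self.clip
        return float(np.clip(self.intercept + self.slope * x, lo, hi))


@dataclass(frozen=True)
class CohortConfig:
    n_players: int = 20
    games_per_player: int = 20
    total_time_s: float = 300.0
    rating_range: tuple[float, float] = (1000.0, 2000.0)
    density_map: AffineMap = field(default_factory=lambda: AffineMap(0.30, 0.25, (0.2, 0.65)))
    radius_map: AffineMap = field(default_factory=lambda: AffineMap(6.5, -3.0, (1.0, 10.0)))
    dt_map: AffineMap = field(default_factory=lambda: AffineMap(90.0, 0.0, (10.0, 150.0)))
    model_kind: str = "obstacles"
    remaining_floor_s: float = 0.0
    master_seed: int = 0

    def __post_init__(self):
        if self.n_players < 1 or self.games_per_player < 1:
            raise InvalidParameterError("n_players and games_per_player must be >= 1")
        if self.model_kind not in ("obstacles", "ddm"):
            raise InvalidParameterError(f"unknown model_kind {self.model_kind!r}")
        if not self.rating_range[0] < self.rating_range[1]:
            raise InvalidParameterError("rating_range must be increasing")

    def params_for_rating(self, rating: float):
        lo, hi = self.rating_range
        x = (rating - lo) / (hi - lo)
        radius = int(np.floor(self.radius_map(x) + 0.5))
        radius = max(1, radius)
        if self.model_kind == "obstacles":
            return ObstaclesParams(radius, self.density_map(x), self.dt_map(x))
        return DDMParams(radius, self.density_map(x), self.dt_map(x))


def gen_rt_sample(model_kind: str, params, n: int, seed: int) -> np.ndarray:
    """``n`` response times in seconds drawn from one model."""
    return batch_fpt(model_kind, params, n_sims=n, seed=seed).rt_s


def gen_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a player population; returns (move table, ground-truth sidecar).

    Each player plays ``games_per_player`` games against the clock: moves
    are drawn from the player's generative model and deducted from the
    remaining time; a move that would drop the clock below
    ``remaining_floor_s`` ends the game and is not recorded. Identical
    config (including ``master_seed``) reproduces the table exactly.
    """
    ss = np.random.SeedSequence(config.master_seed)
    rating_rng = np.random.default_rng(ss.spawn(1)[0])
    lo, hi = config.rating_range
    rows = []
    truth = {}
    dropped = 0
    for i in range(config.n_players):
        pid = f"p{i:04d}"
        rating = float(rating_rng.uniform(lo, hi))
        params = config.params_for_rating(rating)
        player_seed = int(np.random.SeedSequence([config.master_seed, 7, i]).generate_state(1)[0])
        truth[pid] = {
            "rating": rating,
            "model": config.model_kind,
            "radius_R": params.radius_R,
            "dt_ms": params.dt_ms,
            "seed": player_seed,
            **(
                {"obstacle_density_q": params.obstacle_density_q}
                if config.model_kind == "obstacles"
                else {"epsilon": params.epsilon}
            ),
        }
        # draw RTs in chunks and consume them sequentially across games
        buf = iter(())
        chunk = 0

        def next_rt():
            nonlocal buf, chunk
            for rt in buf:
                return rt
            chunk += 1
            buf = iter(
                gen_rt_sample(
                    config.model_kind,
                    params,
                    max(4096, int(2 * config.total_time_s)),
                    seed=player_seed + chunk,
                )
            )
            return next(buf)

        for g in range(config.games_per_player):
            gid = f"{pid}-g{g:04d}"
            remaining = config.total_time_s
            while True:
                rt = float(next_rt())
                if remaining - rt < config.remaining_floor_s:
                    dropped += 1
                    break
                rows.append((pid, rating, gid, config.total_time_s, remaining, rt))
                remaining -= rt
    table = pd.DataFrame(
        rows,
        columns=["player_id", "rating", "game_id", "total_time_s", "remaining_time_s", "rt_s"],
    )
    truth["_meta"] = {"n_dropped_records": dropped, "master_seed": config.master_seed}
    return table, truth
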