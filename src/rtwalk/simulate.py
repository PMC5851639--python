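"""First-passage-time simulation for both response-time models.

A walk starts at the origin and ends on first contact with the absorbing
region (Euclidean distance >= R). Every iteration consumes one time step
``dt_ms``, including steps rejected by the obstacle reflection rule or the
biased-walk acceptance rule; the returned step count is therefore the
response time in units of ``dt_ms``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from . import _kernels
from .errors import ConnectivityError, InvalidParameterError, RunawayWalkError
from .grid import DDMParams, ObstacleGrid, ObstaclesParams, is_connected

__all__ = [
    "FPTSample",
    "DEFAULT_STEP_CAP",
    "DEFAULT_N_SIMS",
    "acceptance_cost",
    "walk_fpt_obstacles",
    "walk_fpt_ddm",
    "batch_fpt",
]

DEFAULT_STEP_CAP = 10_000_000
#: batch size used throughout the fitting pipeline
DEFAULT_N_SIMS = 75_000
DEFAULT_MAX_RETRIES = 10_000

ModelParams = Union[ObstaclesParams, DDMParams]


@dataclass(frozen=True)
class FPTSample:
    """A batch of simulated first-passage times.

    ``steps[i]`` is the iteration count of walk ``i``; response times in
    milliseconds are ``steps * dt_ms``.
    """

    steps: np.ndarray
    dt_ms: float
    model_kind: str
    params: ModelParams
    seed: int
    n_grid_resamples: int = 0

    def __post_init__(self):
        steps = np.asarray(self.steps, dtype=np.int64)
        if steps.size and steps.min() < 1:
            raise InvalidParameterError("all first-passage times must be >= 1 step")
        object.__setattr__(self, "steps", steps)

    @property
    def rt_ms(self) -> np.ndarray:
        return self.steps * float(self.dt_ms)

    @property
    def rt_s(self) -> np.ndarray:
        return self.steps * (float(self.dt_ms) / 1000.0)

    def meta(self) -> dict:
        p = self.params
        return {
            "model": self.model_kind,
            "radius_R": p.radius_R,
            "dt_ms": p.dt_ms,
            **(
                {"obstacle_density_q": p.obstacle_density_q}
                if isinstance(p, ObstaclesParams)
                else {"epsilon": p.epsilon}
            ),
            "seed": self.seed,
            "n_sims": int(self.steps.size),
            "n_grid_resamples": int(self.n_grid_resamples),
        }


def acceptance_cost(displacement_from_origin, proposed_step) -> float:
    """Directional cost of a proposed unit step.

    ``C = (1 - cos theta) / 2`` where ``theta`` is the angle between the
    displacement-from-origin and the proposed step: 0 for a radially
    outward move, 1 for radially inward, 0.5 perpendicular.

    Raises
    ------
    InvalidParameterError
        If the walker is at the origin (direction undefined; callers
        accept such proposals unconditionally) or the step is not a unit
        lattice step.
    """
    z = np.asarray(displacement_from_origin, dtype=float)
    s = np.asarray(proposed_step, dtype=float)
    if z.shape != (2,) or s.shape != (2,):
        raise InvalidParameterError("expected 2-vectors")
    if not (abs(s[0]) + abs(s[1]) == 1.0 and s[0] * s[1] == 0.0):
        raise InvalidParameterError(f"proposed_step must be a unit lattice step, got {s}")
    nz = float(np.hypot(z[0], z[1]))
    if nz == 0.0:
        raise InvalidParameterError("walker at origin: acceptance cost undefined")
    return 0.5 * (1.0 - float(z @ s) / nz)


def _check_steps(steps: np.ndarray, context: str):
    bad = np.flatnonzero(steps == -1)
    if bad.size:
        raise RunawayWalkError(
            f"walk {bad[0]} exceeded the step cap ({context})", walk_index=int(bad[0])
        )
    lost = np.flatnonzero(steps == -2)
    if lost.size:
        raise ConnectivityError(
            f"grid resampling exhausted max_retries at walk {lost[0]} ({context})"
        )


def walk_fpt_obstacles(
    params: ObstaclesParams,
    grid: ObstacleGrid,
    rng: np.random.Generator,
    step_cap: int = DEFAULT_STEP_CAP,
) -> int:
    """One walk to absorption on a fixed grid; returns the step count."""
    if not is_connected(grid):
        raise ConnectivityError("grid has no open path to the absorbing boundary")
    steps = _kernels._batch_obstacles_quenched(
        grid.occupancy, grid.radius_R, 1, step_cap, rng
    )
    _check_steps(steps, "obstacles walk")
    return int(steps[0])


def walk_fpt_ddm(
    params: DDMParams,
    rng: np.random.Generator,
    step_cap: int = DEFAULT_STEP_CAP,
) -> int:
    """One biased walk to absorption; returns the step count."""
    steps = _kernels._batch_ddm(params.radius_R, float(params.epsilon), 1, step_cap, rng)
    _check_steps(steps, "ddm walk")
    return int(steps[0])


def batch_fpt(
    model_kind: str,
    params: ModelParams,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    disorder_mode: str = "annealed",
    grid: ObstacleGrid | None = None,
    step_cap: int = DEFAULT_STEP_CAP,
    max_retries: int = DEFAULT_MAX_RETRIES,
    total_retry_cap: int | None = None,
) -> FPTSample:
    """Simulate ``n_sims`` independent first-passage times.

    Parameters
    ----------
    model_kind : {"obstacles", "ddm"}
    disorder_mode : {"annealed", "quenched"}
        Annealed draws a fresh connected grid for every walk; quenched
        uses one grid for the whole batch (``grid`` if given, otherwise
        the first connected realization seeded from ``seed``).
    total_retry_cap : int, optional
        Batch-wide bound on rejected (disconnected) grid realizations in
        annealed mode; defaults to ``50 * n_sims``. Exhausting it raises
        :class:`ConnectivityError`.
    """
    if n_sims < 1:
        raise InvalidParameterError(f"n_sims must be >= 1, got {n_sims}")
    rng = np.random.default_rng(seed)
    resamples = 0
    if model_kind == "ddm":
        if not isinstance(params, DDMParams):
            raise InvalidParameterError("model_kind 'ddm' requires DDMParams")
        steps = _kernels._batch_ddm(params.radius_R, float(params.epsilon), n_sims, step_cap, rng)
    elif model_kind == "obstacles":
        if not isinstance(params, ObstaclesParams):
            raise InvalidParameterError("model_kind 'obstacles' requires ObstaclesParams")
        if disorder_mode == "annealed" and grid is None:
            if total_retry_cap is None:
                total_retry_cap = 50 * n_sims
            steps, resamples = _kernels._batch_obstacles_annealed(
                params.radius_R,
                float(params.obstacle_density_q),
                n_sims,
                step_cap,
                max_retries,
                total_retry_cap,
                rng,
            )
        elif disorder_mode == "quenched" or grid is not None:
            if grid is None:
                from .grid import sample_connected_grid

                grid, resamples = sample_connected_grid(params, seed, max_retries)
            elif not is_connected(grid):
                raise ConnectivityError("supplied grid is not connected")
            steps = _kernels._batch_obstacles_quenched(
                grid.occupancy, grid.radius_R, n_sims, step_cap, rng
            )
        else:
            raise InvalidParameterError(f"unknown disorder_mode {disorder_mode!r}")
    else:
        raise InvalidParameterError(f"unknown model_kind {model_kind!r}")
    _check_steps(steps, f"{model_kind} batch")
    return FPTSample(
        steps=steps,
        dt_ms=params.dt_ms,
        model_kind=model_kind,
        params=params,
        seed=int(seed),
        n_grid_resamples=int(resamples),
    )
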