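"""Fit either walker model to a target RT histogram by JSD minimization.

The search mirrors the two-level scheme used for response-time fitting:
exhaustive enumeration of the integer boundary radius, and nonlinear
optimization (Nelder-Mead) over the continuous parameters. The objective
is a *stochastic simulation*; to make it a deterministic surface for the
optimizer, every evaluation derives its RNG seed from the base seed and
the walk-determining parameters (common random numbers).

``dt_ms`` never changes the walk itself - it only rescales a step sample
into the histogram bins - so for every simulated shape parameter the best
``dt_ms`` is found by an exhaustive profile over a fine grid. Nelder-Mead
then only has to search the one genuinely stochastic axis (obstacle
density or acceptance noise), where it is reliable. The profile sidesteps
the staircase ruggedness that a joint 2-D simplex search exhibits on
common-random-number surfaces.
"""

from __future__ import annotations

import hashlib
import json
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .dist import DEFAULT_BIN_WIDTH_S, DEFAULT_CAP_S, RTHistogram, bin_rt
from .errors import ConnectivityError, FitFailureError, InvalidParameterError
from .grid import DDMParams, ObstaclesParams
from .simulate import DEFAULT_N_SIMS, batch_fpt

__all__ = [
    "FitSpace",
    "FitResult",
    "derived_seed",
    "objective_jsd",
    "fit_model",
    "cross_validate",
]

_LN2 = float(np.log(2.0))

#: continuous-box defaults per model kind: shape = density q or noise epsilon
_SHAPE_BOUNDS = {
    "obstacles": (0.2, 0.65),
    "ddm": (1e-3, 0.25),
}


@dataclass(frozen=True)
class FitSpace:
    """Search space and evaluation budget for one model fit.

    ``radius_values`` is scanned exhaustively. The shape parameter
    (obstacle density or acceptance noise) is screened on a coarse grid of
    ``coarse_shape_points`` at the ``coarse_sims`` budget, then the
    ``refine_top_k`` best radii are refined with Nelder-Mead from
    ``n_starts`` deterministic starts at the full ``sims_per_eval``
    budget. ``dt_ms`` is profiled exhaustively (steps ``dt_step_coarse_ms``
    / ``dt_step_refine_ms``) at every shape evaluation.
    """

    radius_values: tuple = tuple(range(1, 11))
    shape_bounds: tuple = (0.2, 0.65)
    dt_bounds_ms: tuple = (10.0, 150.0)
    sims_per_eval: int = DEFAULT_N_SIMS
    coarse_sims: int | None = None
    coarse_shape_points: int = 13
    refine_top_k: int = 3
    dt_step_coarse_ms: float = 2.0
    dt_step_refine_ms: float = 1.0
    base_seed: int = 0
    n_starts: int = 2
    nm_max_iter: int = 25
    nm_xatol: float = 0.005
    nm_fatol: float = 1e-7
    disorder_mode: str = "annealed"

    def __post_init__(self):
        if len(self.radius_values) == 0 or any(
            int(r) != r or r < 1 for r in self.radius_values
        ):
            raise InvalidParameterError("radius_values must be positive integers")
        for lo, hi in (self.shape_bounds, self.dt_bounds_ms):
            if not lo < hi:
                raise InvalidParameterError("bounds must satisfy lo < hi")
        if self.sims_per_eval < 1 or self.n_starts < 1:
            raise InvalidParameterError("sims_per_eval and n_starts must be >= 1")
        if self.coarse_sims is not None and self.coarse_sims < 1:
            raise InvalidParameterError("coarse_sims must be >= 1")
        if self.refine_top_k < 1 or self.coarse_shape_points < 2:
            raise InvalidParameterError("refine_top_k >= 1 and coarse_shape_points >= 2 required")

    @property
    def effective_coarse_sims(self) -> int:
        if self.coarse_sims is not None:
            return min(self.coarse_sims, self.sims_per_eval)
        return min(max(self.sims_per_eval // 6, 5000), self.sims_per_eval)

    @classmethod
    def for_model(cls, model_kind: str, **overrides) -> "FitSpace":
        if model_kind not in _SHAPE_BOUNDS:
            raise InvalidParameterError(f"unknown model_kind {model_kind!r}")
        overrides.setdefault("shape_bounds", _SHAPE_BOUNDS[model_kind])
        return cls(**overrides)


@dataclass(frozen=True)
class FitResult:
    model_kind: str
    params: ObstaclesParams | DDMParams
    objective: float
    per_radius: dict = field(repr=False)
    ks_D: float = float("nan")
    n_evals: int = 0
    seed: int = 0
    sims_per_eval: int = 0

    def to_json(self) -> str:
        p = self.params
        return json.dumps(
            {
                "schema_version": 1,
                "model": self.model_kind,
                "params": {
                    "radius_R": p.radius_R,
                    "dt_ms": p.dt_ms,
                    **(
                        {"obstacle_density_q": p.obstacle_density_q}
                        if isinstance(p, ObstaclesParams)
                        else {"epsilon": p.epsilon}
                    ),
                },
                "objective_jsd_nats": self.objective,
                "ks_D": self.ks_D,
                "n_evals": self.n_evals,
                "seed": self.seed,
                "sims_per_eval": self.sims_per_eval,
                "per_radius": {str(r): rec for r, rec in sorted(self.per_radius.items())},
            },
            indent=2,
        )


def derived_seed(base_seed: int, model_kind: str, radius_R: int, shape: float) -> int:
    """Deterministic per-evaluation seed from the walk-determining parameters.

    ``dt_ms`` is deliberately excluded: it only rescales step counts, so
    evaluations differing in ``dt_ms`` alone share one simulated sample.
    """
    key = f"{base_seed}|{model_kind}|{int(radius_R)}|{float(shape):.12e}"
    return int.from_bytes(hashlib.blake2b(key.encode(), digest_size=8).digest(), "big") >> 1


class _StepCache:
    """Tiny FIFO cache of simulated step samples keyed by walk parameters."""

    def __init__(self, maxsize: int = 64):
        self._data: OrderedDict = OrderedDict()
        self.maxsize = maxsize

    def get_steps(self, model_kind, radius, shape, n_sims, base_seed, disorder_mode):
        key = (model_kind, int(radius), round(float(shape), 14), n_sims, base_seed, disorder_mode)
        if key in self._data:
            return self._data[key]
        seed = derived_seed(base_seed, model_kind, radius, shape)
        if model_kind == "obstacles":
            params = ObstaclesParams(radius_R=radius, obstacle_density_q=shape, dt_ms=1.0)
        else:
            params = DDMParams(radius_R=radius, epsilon=shape, dt_ms=1.0)
        sample = batch_fpt(
            model_kind, params, n_sims=n_sims, seed=seed, disorder_mode=disorder_mode
        )
        self._data[key] = sample.steps
        while len(self._data) > self.maxsize:
            self._data.popitem(last=False)
        return sample.steps


_GLOBAL_CACHE = _StepCache()


def _hist_probs_from_steps(steps, dt_ms, edges):
    """Bin step counts (scaled to seconds) onto a uniform-edge histogram."""
    width = edges[1] - edges[0]
    n_bins = edges.size - 1
    rt_s = steps * (dt_ms / 1000.0)
    # same edge nudge as dist.bin_rt so model and target bin identically
    idx = np.clip(np.floor(rt_s / width + 1e-9).astype(np.int64), 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins) / steps.size


def _jsd_probs(p, q) -> float:
    m = 0.5 * (p + q)
    sp_ = p > 0
    sq_ = q > 0
    return float(
        0.5 * np.sum(p[sp_] * np.log(p[sp_] / m[sp_]))
        + 0.5 * np.sum(q[sq_] * np.log(q[sq_] / m[sq_]))
    )


def _best_dt_for_steps(steps, target_probs, edges, dt_lo, dt_hi, dt_step) -> tuple[float, float]:
    """Profile the time-per-step axis exhaustively; returns (dt, objective).

    Works on the unique step counts and their multiplicities, so each dt
    candidate costs O(n_unique) rather than O(n_sims).
    """
    vals, counts = np.unique(steps, return_counts=True)
    weights = counts / steps.size
    width = edges[1] - edges[0]
    n_bins = edges.size - 1
    best_dt, best_val = dt_lo, np.inf
    for dt in np.arange(dt_lo, dt_hi + 0.5 * dt_step, dt_step):
        dt = float(min(dt, dt_hi))
        idx = np.clip((vals * (dt / 1000.0) / width + 1e-9).astype(np.int64), 0, n_bins - 1)
        probs = np.bincount(idx, weights=weights, minlength=n_bins)
        val = _jsd_probs(target_probs, probs)
        if val < best_val:
            best_val, best_dt = val, dt
    return best_dt, best_val


def _uniform_edges_or_raise(target: RTHistogram) -> np.ndarray:
    edges = target.bin_edges
    widths = np.diff(edges)
    if not np.allclose(widths, widths[0], rtol=1e-9, atol=0):
        raise InvalidParameterError("fitting requires uniform-width target bins")
    return edges


def objective_jsd(
    model_kind: str,
    params: ObstaclesParams | DDMParams,
    target: RTHistogram,
    sims_per_eval: int = DEFAULT_N_SIMS,
    seed: int = 0,
    disorder_mode: str = "annealed",
    _cache: _StepCache | None = None,
) -> float:
    """JSD (nats) between the target histogram and a simulated histogram.

    The simulation seed is derived deterministically from ``seed`` and the
    parameters, so identical calls return identical values.
    """
    edges = _uniform_edges_or_raise(target)
    shape = (
        params.obstacle_density_q if isinstance(params, ObstaclesParams) else params.epsilon
    )
    cache = _cache if _cache is not None else _GLOBAL_CACHE
    steps = cache.get_steps(
        model_kind, params.radius_R, shape, sims_per_eval, seed, disorder_mode
    )
    model_probs = _hist_probs_from_steps(steps, params.dt_ms, edges)
    return _jsd_probs(target.probabilities, model_probs)


def fit_model(
    model_kind: str,
    target: RTHistogram,
    space: FitSpace | None = None,
    seed: int | None = None,
) -> FitResult:
    """Global JSD fit: exhaustive over radius, profiled search over the rest.

    A parameter point whose grid ensemble cannot reach the boundary
    (dense-obstacle regime) scores the maximal JSD ``ln 2`` instead of
    aborting the search.
    """
    if space is None:
        space = FitSpace.for_model(model_kind)
    if seed is None:
        seed = space.base_seed
    if int(np.count_nonzero(target.probabilities)) < 2:
        raise FitFailureError("degenerate target: fewer than 2 occupied bins")
    edges = _uniform_edges_or_raise(target)
    tp = target.probabilities
    (s_lo, s_hi) = space.shape_bounds
    (d_lo, d_hi) = space.dt_bounds_ms
    cache = _StepCache(maxsize=128)
    per_radius: dict[int, dict] = {}
    n_evals = 0

    def evaluate(radius, u_shape, n_sims, dt_step, rad_best, trace):
        """One profiled objective evaluation at normalized shape u."""
        nonlocal n_evals
        shape = s_lo + float(np.clip(u_shape, 0.0, 1.0)) * (s_hi - s_lo)
        try:
            steps = cache.get_steps(
                model_kind, radius, shape, n_sims, seed, space.disorder_mode
            )
            dt, val = _best_dt_for_steps(steps, tp, edges, d_lo, d_hi, dt_step)
        except ConnectivityError:
            dt, val = d_lo, _LN2
        n_evals += 1
        if val < rad_best["obj"]:
            rad_best.update(obj=val, shape=shape, dt=dt)
        trace.append(rad_best["obj"])
        return val

    # stage 1: coarse screen of every radius
    coarse_sims = space.effective_coarse_sims
    u_grid = np.linspace(0.0, 1.0, space.coarse_shape_points)
    for radius in space.radius_values:
        radius = int(radius)
        rad_best = {"obj": np.inf, "shape": None, "dt": None}
        trace: list[float] = []
        for u in u_grid:
            evaluate(radius, u, coarse_sims, space.dt_step_coarse_ms, rad_best, trace)
        per_radius[radius] = {
            "objective": rad_best["obj"],
            "shape": rad_best["shape"],
            "dt_ms": rad_best["dt"],
            "n_evals": len(trace),
            "trace_best": trace,
            "refined": False,
        }

    ranked = sorted(
        (r for r in per_radius if np.isfinite(per_radius[r]["objective"])),
        key=lambda r: per_radius[r]["objective"],
    )
    if not ranked:
        raise FitFailureError("no parameter point achieved a finite objective", trace=per_radius)

    # stage 2: Nelder-Mead refinement of the best radii at full budget
    best = {"obj": np.inf, "radius": None, "shape": None, "dt": None}
    spacing = 1.0 / (space.coarse_shape_points - 1)
    for radius in ranked[: space.refine_top_k]:
        rec = per_radius[radius]
        rad_best = {"obj": np.inf, "shape": None, "dt": None}
        trace = []
        u_best = (rec["shape"] - s_lo) / (s_hi - s_lo)
        offsets = [0.0, -spacing, spacing, -2 * spacing, 2 * spacing]
        starts = [float(np.clip(u_best + o, 0.0, 1.0)) for o in offsets[: space.n_starts]]

        def f(u, radius=radius, rad_best=rad_best, trace=trace):
            return evaluate(
                radius, u[0], space.sims_per_eval, space.dt_step_refine_ms, rad_best, trace
            )

        for u0 in starts:
            optimize.minimize(
                f,
                np.asarray([u0]),
                method="Nelder-Mead",
                bounds=[(0.0, 1.0)],
                options={
                    "maxiter": space.nm_max_iter,
                    "xatol": space.nm_xatol,
                    "fatol": space.nm_fatol,
                },
            )
        rec.update(
            objective=rad_best["obj"],
            shape=rad_best["shape"],
            dt_ms=rad_best["dt"],
            n_evals=rec["n_evals"] + len(trace),
            refine_trace_best=trace,
            refined=True,
        )
        if rad_best["obj"] < best["obj"]:
            best.update(
                obj=rad_best["obj"], radius=radius, shape=rad_best["shape"], dt=rad_best["dt"]
            )

    if not np.isfinite(best["obj"]) or best["radius"] is None:
        raise FitFailureError("refinement failed to find a finite objective", trace=per_radius)

    if model_kind == "obstacles":
        params = ObstaclesParams(best["radius"], best["shape"], best["dt"])
    else:
        params = DDMParams(best["radius"], best["shape"], best["dt"])
    # KS statistic of the best fit's binned distribution against the target
    steps = cache.get_steps(
        model_kind, best["radius"], best["shape"], space.sims_per_eval, seed, space.disorder_mode
    )
    model_probs = _hist_probs_from_steps(steps, best["dt"], edges)
    ks_D = float(np.max(np.abs(np.cumsum(tp) - np.cumsum(model_probs))))
    return FitResult(
        model_kind=model_kind,
        params=params,
        objective=float(best["obj"]),
        per_radius=per_radius,
        ks_D=ks_D,
        n_evals=n_evals,
        seed=int(seed),
        sims_per_eval=space.sims_per_eval,
    )


def cross_validate(
    samples,
    model_kinds=("obstacles", "ddm"),
    split_fraction: float = 0.8,
    repeats: int = 1000,
    seed: int = 0,
    spaces: dict | None = None,
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    cap: float = DEFAULT_CAP_S,
) -> dict:
    """Repeated-random-split model comparison on held-out JSD.

    Per repeat: split the RT sample, fit every model on the training
    histogram, and score each fitted model's simulated histogram against
    the held-out histogram. Defaults follow the 80/20 split with 1,000
    repeats; reduce ``repeats`` and the per-model ``FitSpace`` budgets for
    desk-scale runs.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 100:
        raise InvalidParameterError("cross-validation needs >= 100 samples")
    if not 0.0 < split_fraction < 1.0:
        raise InvalidParameterError("split_fraction must be in (0, 1)")
    spaces = spaces or {}
    rng = np.random.default_rng(seed)
    scores: dict[str, list[float]] = {k: [] for k in model_kinds}
    n_failed = 0
    n_train = int(round(split_fraction * x.size))
    for rep in range(repeats):
        perm = rng.permutation(x.size)
        train, test = x[perm[:n_train]], x[perm[n_train:]]
        train_hist = bin_rt(train, bin_width, cap)
        test_hist = bin_rt(test, bin_width, cap)
        rep_scores = {}
        try:
            for kind in model_kinds:
                space = spaces.get(kind, FitSpace.for_model(kind))
                fit = fit_model(kind, train_hist, space, seed=derived_seed(seed, kind, rep + 1, 0.0))
                eval_seed = derived_seed(seed + 1, kind, rep + 1, 1.0)
                sample = batch_fpt(
                    kind,
                    fit.params,
                    n_sims=space.sims_per_eval,
                    seed=eval_seed,
                    disorder_mode=space.disorder_mode,
                )
                model_probs = _hist_probs_from_steps(
                    sample.steps, fit.params.dt_ms, test_hist.bin_edges
                )
                rep_scores[kind] = _jsd_probs(test_hist.probabilities, model_probs)
        except (FitFailureError, ConnectivityError):
            n_failed += 1
            continue
        for kind, v in rep_scores.items():
            scores[kind].append(v)

    out: dict = {"n_repeats": repeats, "n_failed": n_failed, "models": {}}
    arr = {k: np.asarray(v) for k, v in scores.items()}
    for kind in model_kinds:
        wins = np.ones(arr[kind].size, dtype=bool)
        for other in model_kinds:
            if other != kind:
                wins &= arr[kind] < arr[other]
        out["models"][kind] = {
            "mean_test_jsd": float(arr[kind].mean()) if arr[kind].size else float("nan"),
            "win_fraction": float(wins.mean()) if arr[kind].size else float("nan"),
        }
    return out
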