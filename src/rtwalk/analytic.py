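"""Exact first-passage-time references.

Two families of oracles validate the stochastic walkers:

* closed-form 1-D diffusion FPT densities (unit diffusion constant, flux
  ``J = -dP/dx``): the infinite-domain Levy-Smirnov form with its
  ``t**-3/2`` power-law tail, and the bounded absorbing/reflecting domain
  whose tail is exponential;
* the exact absorption-time pmf of the discrete walker on any fixed grid,
  computed from its absorbing Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .errors import InvalidParameterError, InvalidWindowError
from .grid import ObstacleGrid, interior_mask, is_connected

__all__ = [
    "FPTDensity1D",
    "fpt_density_infinite",
    "fpt_density_bounded",
    "exact_fpt_markov",
    "expected_exit_steps",
    "tail_log_slope",
    "TailSlopes",
]

_SERIES_TOL = 1e-10
_MASS_TOL = 1e-10


def fpt_density_infinite(a: float, t) -> np.ndarray | float:
    """Levy-Smirnov FPT density to an absorbing point at distance ``a``.

    ``w(t) = a / sqrt(4 pi t^3) * exp(-a^2 / (4 t))`` for unit diffusion;
    the tail decays as ``t**-1.5``.
    """
    if not a > 0:
        raise InvalidParameterError(f"distance a must be > 0, got {a}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise InvalidParameterError("t must be > 0")
    out = a / np.sqrt(4.0 * np.pi * t_arr**3) * np.exp(-(a * a) / (4.0 * t_arr))
    return out if out.ndim else float(out)


def _series_terms_needed(L: float, t: float) -> float:
    # term n is ~ (2/L) k_n exp(-k_n^2 t), k_n = (n + 1/2) pi / L
    k_needed = np.sqrt(max(np.log(2.0 / (L * _SERIES_TOL)), 1.0) / t + 1.0)
    return k_needed * L / np.pi


def _bounded_series(L: float, y0: float, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    n = 0
    while True:
        k = (n + 0.5) * np.pi / L
        term = (2.0 / L) * ((-1.0) ** n) * k * np.cos(k * y0) * np.exp(-k * k * t)
        out += term
        if (2.0 / L) * k * np.exp(-k * k * t.min()) < _SERIES_TOL or n > 200_000:
            break
        n += 1
    return out


def _bounded_images(L: float, y0: float, t: np.ndarray) -> np.ndarray:
    def psi(x):
        return x / np.sqrt(4.0 * np.pi * t**3) * np.exp(-(x * x) / (4.0 * t))

    out = np.zeros_like(t)
    for m in range(0, 64):
        for sign_m in ((m,) if m == 0 else (m, -m)):
            c = (-1.0) ** (sign_m % 2)
            term = 0.5 * c * (psi(L - y0 - 2 * sign_m * L) + psi(L + y0 - 2 * sign_m * L))
            out += term
        # images 2mL away are negligible once exp(-(2mL)^2/4t) dies
        if m > 0 and np.exp(-((2 * m * L - L) ** 2) / (4.0 * t.max())) < _SERIES_TOL:
            break
    return out


def fpt_density_bounded(x0: float, xT: float, xR: float, t) -> np.ndarray | float:
    """FPT density with absorbing boundary at ``xT``, reflecting at ``xR``.

    Eigenfunction series for large times; method-of-images form when the
    series would need more than ~1e5 terms (small ``t``). The two forms
    agree to ~1e-8 at the internal switch point ``t = L^2 / 20``.
    """
    if xR == xT:
        raise InvalidParameterError("xR must differ from xT")
    lo, hi = min(xR, xT), max(xR, xT)
    if not lo < x0 < hi:
        raise InvalidParameterError(f"x0 must lie strictly between boundaries, got {x0}")
    L = abs(xT - xR)
    y0 = abs(x0 - xR)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr <= 0):
        raise InvalidParameterError("t must be > 0")
    t_switch = L * L / 20.0
    out = np.empty_like(t_arr)
    small = t_arr < t_switch
    if small.any():
        out[small] = _bounded_images(L, y0, t_arr[small])
    if (~small).any():
        out[~small] = _bounded_series(L, y0, t_arr[~small])
    out = np.clip(out, 0.0, None)
    return out if np.asarray(t).ndim else float(out[0])


@dataclass(frozen=True)
class FPTDensity1D:
    """1-D diffusion FPT density; ``xR=None`` means an infinite domain."""

    x0: float
    xT: float
    xR: float | None = None

    def pdf(self, t):
        if self.xR is None:
            return fpt_density_infinite(abs(self.xT - self.x0), t)
        return fpt_density_bounded(self.x0, self.xT, self.xR, t)

    def to_csv(self, path, t_grid) -> None:
        t_grid = np.asarray(t_grid, dtype=float)
        np.savetxt(
            path,
            np.column_stack([t_grid, self.pdf(t_grid)]),
            delimiter=",",
            header="t,density",
            comments="",
        )


def _transition_parts(grid: ObstacleGrid):
    """(Q, a, start): transient transition matrix, absorption probs, origin index."""
    r = grid.radius_R
    occ = grid.occupancy
    open_mask = interior_mask(r) & ~occ
    idx = -np.ones(occ.shape, dtype=np.int64)
    coords = np.argwhere(open_mask)
    idx[coords[:, 0], coords[:, 1]] = np.arange(len(coords))
    n = len(coords)
    a = np.zeros(n)
    rows, cols, vals = [], [], []
    r2 = r * r
    for s, (i, j) in enumerate(coords):
        x, y = i - r, j - r
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nx, ny = x + dx, y + dy
            if nx * nx + ny * ny >= r2:
                a[s] += 0.25
            elif occ[nx + r, ny + r]:
                rows.append(s)
                cols.append(s)
                vals.append(0.25)
            else:
                rows.append(s)
                cols.append(idx[nx + r, ny + r])
                vals.append(0.25)
    Q = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    Q.sum_duplicates()
    return Q, a, int(idx[r, r])


def exact_fpt_markov(grid: ObstacleGrid, mass_tol: float = _MASS_TOL) -> np.ndarray:
    """Exact pmf of the absorption step count on a fixed grid.

    Open interior nodes are the transient states of an absorbing Markov
    chain (uniform over the 4 directions; blocked moves are self-loops).
    Returns ``pmf`` with ``pmf[k] = P(T = k)``; iteration stops when the
    remaining transient mass falls below ``mass_tol``.
    """
    from .errors import ConnectivityError

    if not is_connected(grid):
        raise ConnectivityError("grid is not connected; absorption time is defective")
    Q, a, start = _transition_parts(grid)
    p = np.zeros(Q.shape[0])
    p[start] = 1.0
    pmf = [0.0]
    QT = Q.T.tocsr()
    while p.sum() > mass_tol:
        pmf.append(float(p @ a))
        p = QT @ p
        if len(pmf) > 10_000_000:  # pragma: no cover - defensive
            raise RuntimeError("absorption-time iteration failed to converge")
    return np.asarray(pmf)


def expected_exit_steps(grid: ObstacleGrid) -> float:
    """Exact mean absorption time from the origin: solve (I - Q) m = 1."""
    Q, _a, start = _transition_parts(grid)
    n = Q.shape[0]
    m = sp.linalg.spsolve(sp.identity(n, format="csr") - Q, np.ones(n))
    return float(m[start])


@dataclass(frozen=True)
class TailSlopes:
    """Least-squares slopes of the log-survival curve over a window."""

    semilog_slope: float  # d log S / d t        (exponential scale)
    semilog_se: float
    loglog_slope: float  # d log S / d log t    (power-law scale)
    loglog_se: float
    n_points: int


def tail_log_slope(sample_or_density, window: tuple[float, float]) -> TailSlopes:
    """Fit the tail of a survival curve on both the semilog and log-log scale.

    ``sample_or_density`` is either a 1-D array of observed times or a
    ``(t_grid, density)`` pair; the window is an inclusive time interval
    that must contain at least 10 support points.
    """
    lo, hi = window
    if not lo < hi:
        raise InvalidWindowError(f"invalid window {window}")
    if isinstance(sample_or_density, tuple):
        t_grid, dens = (np.asarray(v, dtype=float) for v in sample_or_density)
        order = np.argsort(t_grid)
        t_grid, dens = t_grid[order], dens[order]
        cdf = np.concatenate([[0.0], np.cumsum(np.diff(t_grid) * 0.5 * (dens[1:] + dens[:-1]))])
        surv = np.clip(1.0 - cdf, 0.0, None)
        keep = (t_grid >= lo) & (t_grid <= hi) & (surv > 0)
        t_pts, s_pts = t_grid[keep], surv[keep]
    else:
        x = np.sort(np.asarray(sample_or_density, dtype=float))
        n = x.size
        surv = 1.0 - np.arange(1, n + 1) / n
        keep = (x >= lo) & (x <= hi) & (surv > 0)
        t_pts, s_pts = x[keep], surv[keep]
    if t_pts.size < 10:
        raise InvalidWindowError(
            f"window {window} holds {t_pts.size} usable points; need >= 10"
        )
    log_s = np.log(s_pts)
    semi = stats.linregress(t_pts, log_s)
    logl = stats.linregress(np.log(t_pts), log_s)
    return TailSlopes(
        semilog_slope=float(semi.slope),
        semilog_se=float(semi.stderr),
        loglog_slope=float(logl.slope),
        loglog_se=float(logl.stderr),
        n_points=int(t_pts.size),
    )
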