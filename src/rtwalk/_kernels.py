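"""Numba kernels for the walkers.

All kernels draw randomness exclusively through ``Generator.random()`` so a
given ``np.random.default_rng(seed)`` yields one reproducible stream. Walks
that exceed the step cap are flagged with ``-1`` in the output array; walks
whose grid resampling exhausts ``max_retries`` are flagged with ``-2``. The
Python wrappers in :mod:`rtwalk.simulate` translate flags into exceptions.
"""

import numpy as np
from numba import njit

# direction table: +x, -x, +y, -y
_DX = np.array([1, -1, 0, 0], dtype=np.int64)
_DY = np.array([0, 0, 1, -1], dtype=np.int64)


@njit(cache=True)
def _fill_grid(occ, r, q, rng):
    """Bernoulli(q) obstacles on non-origin interior nodes of the square."""
    n = 2 * r + 1
    r2 = r * r
    for i in range(n):
        for j in range(n):
            x = i - r
            y = j - r
            if (x != 0 or y != 0) and x * x + y * y < r2:
                occ[i, j] = rng.random() < q
            else:
                occ[i, j] = False


@njit(cache=True)
def _connected(occ, r, seen, stack_x, stack_y):
    """Flood fill from the origin; True if the absorbing rim is reachable."""
    n = 2 * r + 1
    r2 = r * r
    for i in range(n):
        for j in range(n):
            seen[i, j] = False
    top = 0
    stack_x[top] = 0
    stack_y[top] = 0
    top += 1
    seen[r, r] = True
    while top > 0:
        top -= 1
        x = stack_x[top]
        y = stack_y[top]
        for k in range(4):
            nx = x + _DX[k]
            ny = y + _DY[k]
            if nx * nx + ny * ny >= r2:
                return True
            if not seen[nx + r, ny + r] and not occ[nx + r, ny + r]:
                seen[nx + r, ny + r] = True
                stack_x[top] = nx
                stack_y[top] = ny
                top += 1
    return False


@njit(cache=True)
def _walk_on_grid(occ, r, step_cap, rng):
    """Single unbiased walk on a fixed grid; returns steps or -1 on cap."""
    r2 = r * r
    x = 0
    y = 0
    steps = 0
    while steps < step_cap:
        k = int(rng.random() * 4.0)
        if k == 4:  # guard against u == 1.0 edge
            k = 3
        nx = x + _DX[k]
        ny = y + _DY[k]
        steps += 1
        if nx * nx + ny * ny >= r2:
            return steps
        if not occ[nx + r, ny + r]:
            x = nx
            y = ny
    return -1


@njit(cache=True)
def _batch_obstacles_quenched(occ, r, n_sims, step_cap, rng):
    out = np.empty(n_sims, dtype=np.int64)
    for i in range(n_sims):
        out[i] = _walk_on_grid(occ, r, step_cap, rng)
    return out


@njit(cache=True)
def _batch_obstacles_annealed(r, q, n_sims, step_cap, max_retries, total_retry_cap, rng):
    """Fresh connected grid per walk. Returns (steps, total_rejected_grids).

    ``max_retries`` bounds rejections per walk; ``total_retry_cap`` bounds
    them across the whole batch (keeps near-disconnected parameter points
    from stalling an objective evaluation).
    """
    n = 2 * r + 1
    occ = np.zeros((n, n), dtype=np.bool_)
    seen = np.zeros((n, n), dtype=np.bool_)
    stack_x = np.empty(n * n, dtype=np.int64)
    stack_y = np.empty(n * n, dtype=np.int64)
    out = np.empty(n_sims, dtype=np.int64)
    rejected = 0
    for i in range(n_sims):
        if q > 0.0:
            ok = False
            for _attempt in range(max_retries):
                _fill_grid(occ, r, q, rng)
                if _connected(occ, r, seen, stack_x, stack_y):
                    ok = True
                    break
                rejected += 1
                if rejected >= total_retry_cap:
                    break
            if not ok:
                out[i] = -2
                return out[: i + 1], rejected
        out[i] = _walk_on_grid(occ, r, step_cap, rng)
    return out, rejected


@njit(cache=True)
def _batch_ddm(r, eps, n_sims, step_cap, rng):
    """Outward-biased walk: cost C = (1 - cos theta)/2, accept w.p. exp(-C/eps)."""
    r2 = r * r
    out = np.empty(n_sims, dtype=np.int64)
    for i in range(n_sims):
        x = 0
        y = 0
        steps = 0
        res = np.int64(-1)
        while steps < step_cap:
            k = int(rng.random() * 4.0)
            if k == 4:
                k = 3
            dx = _DX[k]
            dy = _DY[k]
            steps += 1
            if x == 0 and y == 0:
                accept = True  # displacement direction undefined at origin
            else:
                c = 0.5 * (1.0 - (x * dx + y * dy) / np.sqrt(x * x + y * y))
                accept = rng.random() < np.exp(-c / eps)
            if accept:
                nx = x + dx
                ny = y + dy
                if nx * nx + ny * ny >= r2:
                    res = steps
                    break
                x = nx
                y = ny
        out[i] = res
    return out
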