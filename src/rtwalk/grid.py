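"""Model parameter types and obstacle-grid realizations.

The decision space is a square lattice with the walker starting at the
origin ``(0, 0)``. Nodes at Euclidean distance ``< R`` from the origin are
*interior*; any node at distance ``>= R`` is absorbing (first contact ends
the walk). A fraction ``q`` of the non-origin interior nodes are reflecting
obstacles: a step into one returns the walker to where it was.

Grids are stored as boolean masks over the ``(2R+1) x (2R+1)`` bounding
square, index ``(i, j) = (x + R, y + R)``; entries outside the interior
disc are always ``False`` (they are absorbing, not occupiable).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import ConnectivityError, InvalidParameterError

__all__ = [
    "ObstaclesParams",
    "DDMParams",
    "ObstacleGrid",
    "build_grid",
    "is_connected",
    "sample_connected_grid",
    "interior_mask",
]

_STEPS4 = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _check_radius(radius_R) -> int:
    if isinstance(radius_R, bool) or not float(radius_R).is_integer():
        raise InvalidParameterError(f"radius_R must be a positive integer, got {radius_R!r}")
    r = int(radius_R)
    if r < 1:
        raise InvalidParameterError(f"radius_R must be >= 1, got {r}")
    return r


@dataclass(frozen=True)
class ObstaclesParams:
    """Parameter triple of the obstacle-walk model.

    Attributes
    ----------
    radius_R : int
        Absorbing-boundary radius in grid-step units.
    obstacle_density_q : float
        Fraction of non-origin interior nodes that are reflecting
        obstacles. ``q = 0`` recovers the pure (obstacle-free) lattice.
    dt_ms : float
        Wall-clock milliseconds per walker iteration.
    """

    radius_R: int
    obstacle_density_q: float
    dt_ms: float

    def __post_init__(self):
        object.__setattr__(self, "radius_R", _check_radius(self.radius_R))
        if not 0.0 <= self.obstacle_density_q <= 1.0:
            raise InvalidParameterError(
                f"obstacle_density_q must be in [0, 1], got {self.obstacle_density_q}"
            )
        if not self.dt_ms > 0:
            raise InvalidParameterError(f"dt_ms must be > 0, got {self.dt_ms}")


@dataclass(frozen=True)
class DDMParams:
    """Parameter triple of the biased-walk (drift-diffusion) model.

    ``epsilon`` is the acceptance noise: a proposed step of directional
    cost ``C`` is accepted with probability ``exp(-C / epsilon)``.
    """

    radius_R: int
    epsilon: float
    dt_ms: float

    def __post_init__(self):
        object.__setattr__(self, "radius_R", _check_radius(self.radius_R))
        if not self.epsilon > 0:
            raise InvalidParameterError(f"epsilon must be > 0, got {self.epsilon}")
        if not self.dt_ms > 0:
            raise InvalidParameterError(f"dt_ms must be > 0, got {self.dt_ms}")


def interior_mask(radius_R: int) -> np.ndarray:
    """Boolean mask of interior nodes (distance < R) on the bounding square."""
    r = _check_radius(radius_R)
    ax = np.arange(-r, r + 1)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    return d2 < r * r


@dataclass(frozen=True)
class ObstacleGrid:
    """One realization of the disordered lattice.

    ``occupancy[x + R, y + R]`` is ``True`` iff node ``(x, y)`` is a
    reflecting obstacle. The origin is never an obstacle and nodes at
    distance >= R are never part of the occupancy.
    """

    radius_R: int
    occupancy: np.ndarray = field(repr=False)
    seed: int = 0

    def __post_init__(self):
        r = _check_radius(self.radius_R)
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != (2 * r + 1, 2 * r + 1):
            raise InvalidParameterError(
                f"occupancy must have shape {(2 * r + 1, 2 * r + 1)}, got {occ.shape}"
            )
        if occ[r, r]:
            raise InvalidParameterError("origin node cannot be an obstacle")
        if (occ & ~interior_mask(r)).any():
            raise InvalidParameterError("nodes at distance >= R are absorbing, not occupiable")
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_interior(self) -> int:
        return int(interior_mask(self.radius_R).sum())

    @property
    def n_obstacles(self) -> int:
        return int(self.occupancy.sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "radius": self.radius_R,
                "seed": self.seed,
                "density": self.n_obstacles / max(self.n_interior - 1, 1),
                "occupancy": self.occupancy.astype(int).ravel().tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ObstacleGrid":
        d = json.loads(text)
        r = int(d["radius"])
        occ = np.asarray(d["occupancy"], dtype=bool).reshape(2 * r + 1, 2 * r + 1)
        return cls(radius_R=r, occupancy=occ, seed=int(d.get("seed", 0)))


def build_grid(radius_R: int, obstacle_density_q: float, seed: int) -> ObstacleGrid:
    """Draw one seeded grid realization.

    Each non-origin interior node is independently an obstacle with
    probability ``obstacle_density_q``. Identical ``(radius_R, q, seed)``
    give a bit-identical mask.
    """
    r = _check_radius(radius_R)
    if not 0.0 <= obstacle_density_q <= 1.0:
        raise InvalidParameterError(f"obstacle_density_q must be in [0, 1], got {obstacle_density_q}")
    rng = np.random.default_rng(seed)
    occ = rng.random((2 * r + 1, 2 * r + 1)) < obstacle_density_q
    occ &= interior_mask(r)
    occ[r, r] = False
    return ObstacleGrid(radius_R=r, occupancy=occ, seed=int(seed))


def is_connected(grid: ObstacleGrid) -> bool:
    """True iff open nodes connect the origin to the absorbing rim.

    Breadth-first search over non-obstacle interior nodes with 4-neighbor
    steps; the grid is connected when some reachable node has a neighbor at
    distance >= R (so the walker can be absorbed in one step).
    """
    r = grid.radius_R
    occ = grid.occupancy
    r2 = r * r
    seen = np.zeros_like(occ, dtype=bool)
    seen[r, r] = True
    queue = deque([(0, 0)])
    while queue:
        x, y = queue.popleft()
        for dx, dy in _STEPS4:
            nx, ny = x + dx, y + dy
            if nx * nx + ny * ny >= r2:
                return True
            if not seen[nx + r, ny + r] and not occ[nx + r, ny + r]:
                seen[nx + r, ny + r] = True
                queue.append((nx, ny))
    return False


def sample_connected_grid(
    params: ObstaclesParams, seed: int, max_retries: int = 10_000
) -> tuple[ObstacleGrid, int]:
    """First seeded realization with an open path to the rim.

    Successive candidate grids use sub-seeds spawned deterministically from
    ``seed``. Returns ``(grid, n_rejected)``; raises
    :class:`ConnectivityError` when ``max_retries`` realizations all fail.
    """
    if max_retries < 1:
        raise InvalidParameterError(f"max_retries must be >= 1, got {max_retries}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max_retries)
    for attempt, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0])
        grid = build_grid(params.radius_R, params.obstacle_density_q, sub_seed)
        if is_connected(grid):
            return grid, attempt
    raise ConnectivityError(
        f"no connected grid in {max_retries} realizations "
        f"(R={params.radius_R}, q={params.obstacle_density_q})",
        rejections=max_retries,
    )
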