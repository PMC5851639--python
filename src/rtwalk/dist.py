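"""Response-time histograms and distribution distances.

Response times are binned on a fixed grid of half-open intervals
``[lo, hi)`` spanning ``[0, cap)``; anything at or beyond the cap is
pooled into the last bin (the clock budget bounds observable times).
Divergences are reported in nats, so the Jensen-Shannon divergence lies
in ``[0, ln 2]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import distributions as _distributions

from .errors import BinningError, DivergenceUndefinedError, EmptyInputError

__all__ = [
    "RTHistogram",
    "DEFAULT_BIN_WIDTH_S",
    "DEFAULT_CAP_S",
    "bin_rt",
    "kl_divergence",
    "jsd",
    "ks_two_sample",
]

DEFAULT_BIN_WIDTH_S = 0.1
DEFAULT_CAP_S = 300.0


@dataclass(frozen=True)
class RTHistogram:
    """A binned response-time probability distribution."""

    bin_edges: np.ndarray
    probabilities: np.ndarray
    n_samples: int = 0

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        if edges.ndim != 1 or probs.ndim != 1 or probs.size != edges.size - 1:
            raise BinningError("need len(probabilities) == len(bin_edges) - 1")
        if np.any(np.diff(edges) <= 0):
            raise BinningError("bin_edges must be strictly increasing")
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-12:
            raise BinningError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def median(self) -> float:
        """Median from the cumulative mass, linearly interpolated in-bin."""
        cum = np.cumsum(self.probabilities)
        i = int(np.searchsorted(cum, 0.5))
        lo, hi = self.bin_edges[i], self.bin_edges[i + 1]
        prev = cum[i - 1] if i else 0.0
        frac = (0.5 - prev) / max(cum[i] - prev, 1e-300)
        return float(lo + frac * (hi - lo))

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.bin_edges[:-1], self.bin_edges[1:], self.probabilities]),
            delimiter=",",
            header="bin_lo,bin_hi,probability",
            comments="",
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "bin_edges": self.bin_edges.tolist(),
                "probabilities": self.probabilities.tolist(),
                "n_samples": self.n_samples,
            }
        )


def bin_rt(
    samples,
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    cap: float = DEFAULT_CAP_S,
) -> RTHistogram:
    """Histogram RT samples (seconds) on fixed-width half-open bins.

    Defaults give 3000 bins of 0.1 s across a 300 s budget; samples at or
    beyond the cap land in the last bin.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise EmptyInputError("cannot bin an empty sample set")
    if not bin_width > 0:
        raise BinningError(f"bin_width must be > 0, got {bin_width}")
    n_bins = int(np.ceil(cap / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    # the 1e-9 nudge keeps values that sit numerically on a bin edge from
    # straddling it depending on how they were computed (e.g. ms round trips)
    idx = np.clip(np.floor(x / bin_width + 1e-9).astype(np.int64), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return RTHistogram(bin_edges=edges, probabilities=counts / x.size, n_samples=int(x.size))


def _check_same_edges(p: RTHistogram, q: RTHistogram):
    if p.bin_edges.size != q.bin_edges.size or not np.allclose(
        p.bin_edges, q.bin_edges, rtol=0, atol=1e-12
    ):
        raise BinningError("histograms do not share bin edges")


def kl_divergence(p: RTHistogram, q: RTHistogram) -> float:
    """Kullback-Leibler divergence ``sum p ln(p/q)`` in nats, 0 ln 0 = 0."""
    _check_same_edges(p, q)
    pp, qq = p.probabilities, q.probabilities
    support = pp > 0
    if np.any(qq[support] == 0):
        raise DivergenceUndefinedError("P has mass where Q has none")
    return float(np.sum(pp[support] * np.log(pp[support] / qq[support])))


def jsd(p: RTHistogram, q: RTHistogram) -> float:
    """Jensen-Shannon divergence in nats: always finite, in [0, ln 2]."""
    _check_same_edges(p, q)
    m = RTHistogram(
        bin_edges=p.bin_edges,
        probabilities=0.5 * (p.probabilities + q.probabilities),
        n_samples=p.n_samples + q.n_samples,
    )
    return 0.5 * kl_divergence(p, m) + 0.5 * kl_divergence(q, m)


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns ``(D, p)`` with ``D = sup |ECDF_a - ECDF_b|`` and ``p`` from the
    asymptotic Kolmogorov distribution at effective size
    ``n_a n_b / (n_a + n_b)``.
    """
    a = np.sort(np.asarray(a, dtype=float).ravel())
    b = np.sort(np.asarray(b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise EmptyInputError("KS test needs two non-empty samples")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    n_eff = a.size * b.size / (a.size + b.size)
    p = float(_distributions.kstwobign.sf(d * np.sqrt(n_eff)))
    return d, min(max(p, 0.0), 1.0)
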