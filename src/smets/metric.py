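"""SMETS: a semi-metric between multivariate time series of any dimensions.

The comparison has two parts. First, every component of the lower-dimensional
series is greedily paired with its most similar counterpart in the other
series (globally smallest cross-distance first, matched components removed),
and the matched distances d are aggregated with a p-norm where p = n, the
smaller dimension. Second, two penalties account for what the matching could
not use: an entropy penalty EP weighting each unmatched component's distance
to its nearest counterpart by its share of Shannon information (constant
traces carry none and cost nothing), and a dimension penalty
P = (m - n)/(m + n) that keeps series of different cardinality apart even
when all unmatched components are flat. The total is

    SMETS(A, B) = ||d||_n + sqrt(EP^2 + P^2).

The result is non-negative, symmetric, reflexive and zero only for identical
(preprocessed) inputs; the triangle inequality holds when the dimensions are
equal — on mixed dimensions SMETS is a semi-metric only.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_SETTINGS, PipelineSettings
from .representation import WaveletRepresentation, represent, representation_distance
from .series import MultivariateSeries, UnivariateSeries, next_power_of_two, z_normalize

__all__ = [
    "MatchResult",
    "EntropyProfile",
    "SmetsBreakdown",
    "greedy_match",
    "p_norm_distance",
    "entropy",
    "entropy_penalty",
    "dimension_penalty",
    "smets_distance",
    "smets_breakdown",
    "cross_distance_matrix",
]


@dataclass(frozen=True)
class MatchResult:
    """Outcome of the greedy partial matching.

    ``pairs`` holds (index in smaller, index in larger, distance) in the
    order the greedy step selected them; ``d`` the matched distances;
    ``unmatched`` each leftover component of the larger series with its
    smallest distance d_j to any component of the smaller series, taken
    from the full pre-removal distance matrix.
    """

    pairs: tuple[tuple[int, int, float], ...]
    d: np.ndarray
    unmatched: tuple[tuple[int, float], ...]
    n: int
    m: int

    def __post_init__(self) -> None:
        if len(self.pairs) != self.n or len(self.unmatched) != self.m - self.n:
            raise ValueError("match bookkeeping inconsistent with dimensions")
        d = np.asarray(self.d, dtype=np.float64)
        if np.any(d < 0) or any(dj < 0 for _, dj in self.unmatched):
            raise ValueError("distances must be non-negative")
        d.setflags(write=False)
        object.__setattr__(self, "d", d)


@dataclass(frozen=True)
class EntropyProfile:
    """Shannon entropy of one component trace, in nats.

    ``entropy`` is 0 for a constant trace and at most ln(q) (all q values
    distinct). ``frequencies`` maps each observed value (or bin center) to
    its empirical frequency.
    """

    name: str
    entropy: float
    length: int
    frequencies: dict[float, float]


def greedy_match(distances: np.ndarray) -> MatchResult:
    """Greedy partial matching on an n x m cross-distance matrix (n <= m).

    Rows index the smaller series. Repeatedly take the globally smallest
    remaining entry (ties broken to the lexicographically smallest
    (row, column)), record it, and retire both its row and column, until
    every row is matched. Columns never matched keep, as d_j, their
    row-wise minimum over the *original* matrix.
    """
    dist = np.asarray(distances, dtype=np.float64)
    if dist.ndim != 2 or dist.size == 0:
        raise ValueError("need a non-empty 2-d distance matrix")
    n, m = dist.shape
    if n > m:
        raise ValueError(f"rows ({n}) must index the smaller series (cols {m})")
    if np.any(dist < 0) or not np.all(np.isfinite(dist)):
        raise ValueError("distances must be finite and non-negative")

    work = dist.copy()
    pairs: list[tuple[int, int, float]] = []
    for _ in range(n):
        flat = int(np.argmin(work))  # row-major argmin = lexicographic tie-break
        i, j = divmod(flat, m)
        pairs.append((i, j, float(dist[i, j])))
        work[i, :] = np.inf
        work[:, j] = np.inf
    matched_cols = {j for _, j, _ in pairs}
    unmatched = tuple(
        (j, float(dist[:, j].min())) for j in range(m) if j not in matched_cols
    )
    return MatchResult(
        pairs=tuple(pairs),
        d=np.array([p[2] for p in pairs]),
        unmatched=unmatched,
        n=n,
        m=m,
    )


def p_norm_distance(match: MatchResult | np.ndarray, p: int | None = None) -> float:
    """(sum d_i^p)^(1/p) with p = n, computed in scaled form for stability."""
    if isinstance(match, MatchResult):
        d, p = match.d, match.n
    else:
        d = np.asarray(match, dtype=np.float64)
        if p is None:
            p = d.size
    if p < 1:
        raise ValueError("p must be >= 1")
    top = float(np.max(d, initial=0.0))
    if top == 0.0:
        return 0.0
    return top * float(np.sum((d / top) ** p)) ** (1.0 / p)


def entropy(series: UnivariateSeries, bins: int = 0) -> EntropyProfile:
    """Shannon entropy of a component from empirical value frequencies.

    With ``bins == 0`` each distinct value is its own outcome — faithful to
    frequencies of the data points themselves, and exactly zero for constant
    traces. For continuous data, where exact frequencies degenerate to the
    uniform distribution, a positive ``bins`` quantizes the range first.
    """
    v = series.values
    if bins > 0 and np.ptp(v) > 0:
        counts, edges = np.histogram(v, bins=bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        counts, keys = counts[keep], centers[keep]
    else:
        keys, counts = np.unique(v, return_counts=True)
    freqs = counts / v.size
    h = float(-np.sum(freqs * np.log(freqs)))
    return EntropyProfile(
        name=series.name,
        entropy=max(h, 0.0),
        length=v.size,
        frequencies={float(k): float(f) for k, f in zip(keys, freqs)},
    )


def entropy_penalty(match: MatchResult, entropies: np.ndarray) -> float:
    """Information-weighted cost of the unmatched components.

    ``entropies`` gives H_j for every component of the larger series,
    indexed like the matrix columns. The penalty is the entropy-weighted
    mean of the d_j: EP = sum_j (H_j / sum_k H_k) d_j over unmatched j.
    It vanishes when nothing is unmatched or when every unmatched trace is
    constant (zero information content).
    """
    if not match.unmatched:
        return 0.0
    H = np.asarray(entropies, dtype=np.float64)
    if H.size != match.m:
        raise ValueError(
            f"need one entropy per component of the larger series "
            f"({match.m}), got {H.size}"
        )
    idx = np.array([j for j, _ in match.unmatched])
    dj = np.array([d for _, d in match.unmatched])
    weights = H[idx]
    total = weights.sum()
    if total == 0.0:
        return 0.0
    return float(np.sum(weights / total * dj))


def dimension_penalty(n: int, m: int) -> float:
    """P = (m - n)/(m + n): 0 for equal dimensions, approaching 1 as they diverge."""
    if n < 1 or m < n:
        raise ValueError(f"need m >= n >= 1, got n={n}, m={m}")
    return (m - n) / (m + n)


@dataclass(frozen=True)
class SmetsBreakdown:
    """SMETS value together with its three ingredients."""

    match: MatchResult
    matched_norm: float
    entropy_penalty: float
    dimension_penalty: float

    @property
    def value(self) -> float:
        return self.matched_norm + float(
            np.hypot(self.entropy_penalty, self.dimension_penalty)
        )


def _prepare(
    series: MultivariateSeries, settings: PipelineSettings, pad_to: int
) -> tuple[list[WaveletRepresentation], np.ndarray]:
    """Representations plus per-component entropies (on pre-padding values)."""
    reps = [represent(c, settings, pad_to=pad_to) for c in series]
    normalized = (z_normalize(c) for c in series) if settings.normalize else iter(series)
    H = np.array([entropy(c, settings.entropy_bins).entropy for c in normalized])
    return reps, H


def cross_distance_matrix(
    reps_small: list[WaveletRepresentation],
    reps_large: list[WaveletRepresentation],
) -> np.ndarray:
    return np.array(
        [[representation_distance(a, b) for b in reps_large] for a in reps_small]
    )


def smets_breakdown(
    a: MultivariateSeries,
    b: MultivariateSeries,
    settings: PipelineSettings = DEFAULT_SETTINGS,
) -> SmetsBreakdown:
    """Full SMETS comparison with intermediate quantities exposed.

    The lower-dimensional argument plays the 'smaller' role (first argument
    on ties); both series are padded to one common power-of-two length so
    their coefficient spaces line up even when their raw lengths differ.
    """
    small, large = (a, b) if a.dimension <= b.dimension else (b, a)
    pad_to = next_power_of_two(max(a.length, b.length))
    reps_s, _ = _prepare(small, settings, pad_to)
    reps_l, H_l = _prepare(large, settings, pad_to)
    match = greedy_match(cross_distance_matrix(reps_s, reps_l))
    return SmetsBreakdown(
        match=match,
        matched_norm=p_norm_distance(match),
        entropy_penalty=entropy_penalty(match, H_l),
        dimension_penalty=dimension_penalty(small.dimension, large.dimension),
    )


def smets_distance(
    a: MultivariateSeries,
    b: MultivariateSeries,
    settings: PipelineSettings = DEFAULT_SETTINGS,
) -> float:
    """SMETS distance ||d||_n + sqrt(EP^2 + P^2) between two models."""
    return smets_breakdown(a, b, settings).value
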