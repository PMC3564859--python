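"""Distance matrices over collections of models, clustering, and the
weighted-average baseline.

The front end the method is normally used through: compute all pairwise
SMETS values over a set of multivariate series, cluster the resulting
matrix agglomeratively, and export the tree. The classical alternative —
collapse each model to a (weighted) average trace and compare those with
the Euclidean distance — is provided as the baseline comparator.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import DEFAULT_SETTINGS, PipelineSettings
from .metric import (
    SmetsBreakdown,
    cross_distance_matrix,
    dimension_penalty,
    entropy_penalty,
    greedy_match,
    p_norm_distance,
    _prepare,
)
from .series import MultivariateSeries, UnivariateSeries, next_power_of_two

__all__ = [
    "DistanceMatrix",
    "LinkageTree",
    "build_distance_matrix",
    "average_baseline",
    "baseline_distance_matrix",
    "hierarchical_cluster",
    "plot_heatmap",
]

LINKAGE_METHODS = ("single", "complete", "average")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        k = len(self.labels)
        if v.shape != (k, k):
            raise ValueError(f"matrix shape {v.shape} does not fit {k} labels")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        with np.errstate(invalid="ignore"):
            if np.any(v < 0):
                raise ValueError("distances must be non-negative")
        if not np.allclose(v, v.T, rtol=0, atol=1e-12, equal_nan=True):
            raise ValueError("matrix is not symmetric within 1e-12")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index_label="series")


def build_distance_matrix(
    collection: Sequence[MultivariateSeries],
    settings: PipelineSettings = DEFAULT_SETTINGS,
) -> DistanceMatrix:
    """All pairwise SMETS distances over a collection.

    Every series is padded to the collection-wide power-of-two length and
    represented once; each cell then reuses the prepared representations.
    """
    if len(collection) < 2:
        raise ValueError("need at least two series")
    labels = [s.name for s in collection]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate series labels in collection: {sorted(labels)}")
    pad_to = next_power_of_two(max(s.length for s in collection))
    prepared = [_prepare(s, settings, pad_to) for s in collection]
    dims = [s.dimension for s in collection]
    k = len(collection)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            si, sj = (i, j) if dims[i] <= dims[j] else (j, i)
            reps_s, _ = prepared[si]
            reps_l, H_l = prepared[sj]
            match = greedy_match(cross_distance_matrix(reps_s, reps_l))
            value = p_norm_distance(match) + np.hypot(
                entropy_penalty(match, H_l), dimension_penalty(dims[si], dims[sj])
            )
            out[i, j] = out[j, i] = value
    return DistanceMatrix(labels=tuple(labels), values=out)


def average_baseline(
    series: MultivariateSeries, weights: Sequence[float] | None = None
) -> UnivariateSeries:
    """Collapse a model to the (weighted) pointwise mean of its components."""
    stack = np.vstack([c.values for c in series])
    if weights is not None:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (series.dimension,):
            raise ValueError(
                f"{series.dimension} components but {w.size} weights"
            )
        if w.sum() == 0:
            raise ValueError("weights sum to zero")
        mean = np.average(stack, axis=0, weights=w)
    else:
        mean = stack.mean(axis=0)
    return UnivariateSeries(f"{series.name}_mean", mean)


def baseline_distance_matrix(
    collection: Sequence[MultivariateSeries],
    weights: Sequence[Sequence[float]] | None = None,
) -> DistanceMatrix:
    """Euclidean distances between the models' (weighted) average traces."""
    if len(collection) < 2:
        raise ValueError("need at least two series")
    if len({s.length for s in collection}) != 1:
        raise ValueError("baseline comparison requires a common series length")
    labels = [s.name for s in collection]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate series labels in collection")
    means = [
        average_baseline(s, None if weights is None else weights[i]).values
        for i, s in enumerate(collection)
    ]
    k = len(means)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = float(np.linalg.norm(means[i] - means[j]))
    return DistanceMatrix(labels=tuple(labels), values=out)


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative clustering result over a labelled distance matrix."""

    labels: tuple[str, ...]
    linkage: np.ndarray
    method: str

    def to_newick(self) -> str:
        from skbio.tree import TreeNode  # deferred: heavy import

        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.labels))
        return str(tree)

    def merge_table(self) -> pd.DataFrame:
        """One row per merge: the two clusters joined, their distance, size."""
        return pd.DataFrame(
            self.linkage,
            columns=["cluster_a", "cluster_b", "distance", "size"],
        ).astype({"cluster_a": int, "cluster_b": int, "size": int})

    def write(self, newick_path: str | Path, table_path: str | Path | None = None) -> None:
        Path(newick_path).write_text(self.to_newick())
        if table_path is not None:
            self.merge_table().to_csv(table_path, sep="\t", index=False)


def hierarchical_cluster(
    matrix: DistanceMatrix, method: str = "average"
) -> LinkageTree:
    """Agglomerative hierarchical clustering of a SMETS distance matrix."""
    if method not in LINKAGE_METHODS:
        raise ValueError(f"method must be one of {LINKAGE_METHODS}")
    if np.any(np.isnan(matrix.values)):
        raise ValueError("distance matrix contains NaN")
    condensed = squareform(matrix.values, checks=False)
    linkage = hierarchy.linkage(condensed, method=method)
    return LinkageTree(labels=matrix.labels, linkage=linkage, method=method)


def plot_heatmap(matrix: DistanceMatrix, path: str | Path) -> None:
    """Grayscale heat map of a distance matrix (darker = closer)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.6 * len(matrix.labels) + 2,) * 2)
    im = ax.imshow(matrix.values, cmap="gray")
    ax.set_xticks(range(len(matrix.labels)), matrix.labels, rotation=90)
    ax.set_yticks(range(len(matrix.labels)), matrix.labels)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
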