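"""Containers and preprocessing for uni- and multivariate time series.

A *multivariate* series here is a named, ordered bag of univariate component
traces sampled at common time points — one dynamical model, one stock index,
one recording. Components are assumed equally spaced in time; timestamps are
checked on ingestion and then discarded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UnivariateSeries",
    "MultivariateSeries",
    "z_normalize",
    "next_power_of_two",
    "pad_to_power_of_two",
    "read_series_csv",
]


@dataclass(frozen=True)
class UnivariateSeries:
    """One component trace: a name and an equally spaced sequence of values.

    Parameters
    ----------
    name
        Component label, unique within its parent multivariate series.
    values
        Real sample values; at least two, all finite. Stored as an
        immutable float64 array.
    """

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size < 2:
            raise ValueError(
                f"component {self.name!r}: need a 1-d sequence of length >= 2, "
                f"got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError(f"component {self.name!r} contains non-finite values")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class MultivariateSeries:
    """An ordered, named collection of component traces (one 'model')."""

    name: str
    components: tuple[UnivariateSeries, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if not comps:
            raise ValueError(f"series {self.name!r} has no components")
        lengths = {len(c) for c in comps}
        if len(lengths) != 1:
            raise ValueError(
                f"series {self.name!r}: components differ in length ({sorted(lengths)})"
            )
        names = [c.name for c in comps]
        if len(set(names)) != len(names):
            raise ValueError(f"series {self.name!r}: duplicate component names")
        object.__setattr__(self, "components", comps)

    @property
    def dimension(self) -> int:
        """Number of component traces (n for the smaller model in a comparison)."""
        return len(self.components)

    @property
    def length(self) -> int:
        """Number of time points q, common to all components."""
        return len(self.components[0])

    def __iter__(self) -> Iterator[UnivariateSeries]:
        return iter(self.components)

    def __getitem__(self, key: int | str) -> UnivariateSeries:
        if isinstance(key, str):
            for c in self.components:
                if c.name == key:
                    return c
            raise KeyError(key)
        return self.components[key]


def z_normalize(series: UnivariateSeries) -> UnivariateSeries:
    """Subtract the mean and divide by the population standard deviation.

    Constant traces (zero spread) map to all-zeros rather than raising:
    flat components are legitimate model behaviour and must survive
    preprocessing with zero information content.
    """
    v = series.values
    mu = v.mean()
    sigma = v.std()  # population (divide-by-q) form
    if sigma == 0.0:
        return UnivariateSeries(series.name, np.zeros_like(v))
    return UnivariateSeries(series.name, (v - mu) / sigma)


def next_power_of_two(n: int) -> int:
    if n < 1:
        raise ValueError("length must be positive")
    return 1 << (int(n) - 1).bit_length()


def pad_to_power_of_two(
    series: UnivariateSeries, target: int | None = None
) -> UnivariateSeries:
    """Append zeros until the length is a power of two.

    ``target`` may request a larger power of two (used when several series of
    different lengths must share one padded length); it must itself be a power
    of two and at least the series length.
    """
    q = len(series)
    goal = next_power_of_two(q) if target is None else int(target)
    if goal & (goal - 1) or goal < q:
        raise ValueError(f"target {goal} is not a power of two >= length {q}")
    if goal == q:
        return series
    padded = np.zeros(goal)
    padded[:q] = series.values
    return UnivariateSeries(series.name, padded)


def read_series_csv(
    path: str | Path, name: str | None = None, delimiter: str | None = None
) -> MultivariateSeries:
    """Read one multivariate series from a delimited text file.

    Layout: header row of names, first column time (used only for a
    monotonicity/spacing check), each remaining column one component.
    Missing cells are an error. Delimiter is sniffed unless given.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=delimiter, engine="python")
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one component")
    if frame.isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValueError(f"{path}: missing cells in column(s) {bad}")
    t = frame.iloc[:, 0].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: time column is not strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=0):
            logger.warning(
                "%s: non-uniform time spacing; samples will be treated as "
                "equally spaced",
                path,
            )
    comps = tuple(
        UnivariateSeries(str(col), frame[col].to_numpy(dtype=float))
        for col in frame.columns[1:]
    )
    return MultivariateSeries(name or path.stem, comps)
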