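"""Haar wavelet representations of univariate series and distances on them.

A series is compressed to its k largest-magnitude orthonormal Haar DWT
coefficients, kept together with their positions in the full multiresolution
vector. Because the transform is orthonormal, Euclidean distance between two
full coefficient vectors equals the distance between the raw series; dropping
coefficients can only be allowed to *shrink* that distance (the lower-bounding
requirement of indexing representations), which the distance below guarantees
by discounting positions retained on one side only by the other side's
largest dropped magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pywt

from .config import DEFAULT_SETTINGS, PipelineSettings
from .series import UnivariateSeries, next_power_of_two, pad_to_power_of_two, z_normalize

__all__ = [
    "WaveletRepresentation",
    "haar_transform",
    "retain_top_k",
    "truncate_padding_bias",
    "representation_distance",
    "represent",
]


@dataclass(frozen=True)
class WaveletRepresentation:
    """Sparse view of a series in orthonormal Haar coefficient space.

    ``coefficients[i]`` sits at position ``indices[i]`` of the full
    multiresolution vector (approximation first, then detail levels from
    coarsest to finest, so trailing positions are the ones a zero-padded
    tail contaminates). ``threshold`` bounds the magnitude of every
    coefficient that was discarded; it is what keeps distances between
    representations below distances between the underlying series.
    """

    name: str
    coefficients: np.ndarray
    indices: np.ndarray
    source_length: int
    padded_length: int
    threshold: float = 0.0
    fingerprint: tuple | None = None

    def __post_init__(self) -> None:
        coefs = np.asarray(self.coefficients, dtype=np.float64)
        idx = np.asarray(self.indices, dtype=np.intp)
        if coefs.size < 1 or coefs.shape != idx.shape:
            raise ValueError("need >= 1 coefficient with matching indices")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("coefficient indices must be strictly increasing")
        if idx[0] < 0 or idx[-1] >= self.padded_length:
            raise ValueError("coefficient index out of range of the padded length")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        for key, value in (("coefficients", coefs), ("indices", idx)):
            value.setflags(write=False)
            object.__setattr__(self, key, value)

    def __len__(self) -> int:
        return self.coefficients.size


def haar_transform(series: UnivariateSeries | np.ndarray) -> np.ndarray:
    """Full orthonormal Haar DWT of a power-of-two-length series.

    Returns the concatenated multiresolution vector
    ``[cA_L, cD_L, ..., cD_1]`` (coarse to fine), the same length as the
    input. Orthonormality gives Parseval: the coefficient vector has the
    same energy as the input.
    """
    source = series.values if isinstance(series, UnivariateSeries) else series
    values = np.array(source, dtype=np.float64)  # writable copy for pywt
    n = values.size
    if n < 1 or n & (n - 1):
        raise ValueError(
            f"Haar transform needs a power-of-two length, got {n}; "
            "pad_to_power_of_two() first"
        )
    if n == 1:
        return values.astype(float).copy()
    coeffs = pywt.wavedec(values, "haar", mode="periodization")
    return np.concatenate(coeffs)


def retain_top_k(
    coefficients: Sequence[float] | np.ndarray,
    k: int,
    *,
    name: str = "",
    source_length: int | None = None,
    fingerprint: tuple | None = None,
) -> WaveletRepresentation:
    """Keep the k coefficients of largest magnitude, with their positions.

    Ties in magnitude are broken toward the lower index so the choice is
    deterministic. The largest discarded magnitude is recorded as the
    representation's ``threshold``.
    """
    coefs = np.asarray(coefficients, dtype=np.float64)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > coefs.size:
        raise ValueError(f"k={k} exceeds the {coefs.size} available coefficients")
    order = np.lexsort((np.arange(coefs.size), -np.abs(coefs)))
    keep = np.sort(order[:k])
    dropped = np.abs(coefs[order[k:]])
    return WaveletRepresentation(
        name=name,
        coefficients=coefs[keep],
        indices=keep,
        source_length=coefs.size if source_length is None else source_length,
        padded_length=coefs.size,
        threshold=float(dropped.max()) if dropped.size else 0.0,
        fingerprint=fingerprint,
    )


def truncate_padding_bias(
    rep: WaveletRepresentation, target_len: int
) -> WaveletRepresentation:
    """Drop trailing retained symbols (largest transform indices).

    Zero-padding a series contaminates the finest-scale coefficients over
    its tail, which sit at the end of the multiresolution vector; removing
    the trailing retained symbol(s) removes that bias from comparisons.
    """
    if target_len < 1:
        raise ValueError("target_len must be positive")
    if target_len >= len(rep):
        raise ValueError(
            f"target_len={target_len} is not below the current length {len(rep)}"
        )
    dropped = np.abs(rep.coefficients[target_len:])
    return WaveletRepresentation(
        name=rep.name,
        coefficients=rep.coefficients[:target_len],
        indices=rep.indices[:target_len],
        source_length=rep.source_length,
        padded_length=rep.padded_length,
        threshold=max(rep.threshold, float(dropped.max())),
        fingerprint=rep.fingerprint,
    )


def representation_distance(
    a: WaveletRepresentation, b: WaveletRepresentation
) -> float:
    """Euclidean distance in coefficient space, never above the raw distance.

    Positions retained by both sides contribute their exact difference.
    A position retained on one side only is compared against an unknown
    discarded coefficient of magnitude at most the other side's threshold,
    so it contributes ``max(|c| - threshold_other, 0)`` — the smallest
    difference consistent with what was kept. With nothing discarded
    (threshold 0) this is plain union-of-positions with implicit zeros.
    """
    if a.fingerprint != b.fingerprint:
        raise ValueError(
            f"representations built with different pipeline settings: "
            f"{a.fingerprint} vs {b.fingerprint}"
        )
    if a.padded_length != b.padded_length:
        raise ValueError(
            f"representations over different padded lengths: "
            f"{a.padded_length} vs {b.padded_length}"
        )
    ia, ib = a.indices, b.indices
    common, pos_a, pos_b = np.intersect1d(ia, ib, return_indices=True)
    total = float(np.sum((a.coefficients[pos_a] - b.coefficients[pos_b]) ** 2))
    only_a = np.setdiff1d(np.arange(ia.size), pos_a)
    only_b = np.setdiff1d(np.arange(ib.size), pos_b)
    total += float(
        np.sum(np.maximum(np.abs(a.coefficients[only_a]) - b.threshold, 0.0) ** 2)
    )
    total += float(
        np.sum(np.maximum(np.abs(b.coefficients[only_b]) - a.threshold, 0.0) ** 2)
    )
    return float(np.sqrt(total))


def represent(
    series: UnivariateSeries,
    settings: PipelineSettings = DEFAULT_SETTINGS,
    pad_to: int | None = None,
) -> WaveletRepresentation:
    """Run one component through the full preprocessing pipeline.

    normalize -> zero-pad to a power of two (``pad_to`` lets a whole
    comparison or collection share one padded length) -> Haar DWT ->
    keep the k largest-magnitude coefficients -> drop the padding-biased
    tail symbol(s). With the wavelet disabled the normalized, padded
    values themselves serve as the (lossless) representation.
    """
    prepared = z_normalize(series) if settings.normalize else series
    source_length = len(prepared)
    prepared = pad_to_power_of_two(prepared, target=pad_to)
    if not settings.wavelet_enabled:
        return WaveletRepresentation(
            name=series.name,
            coefficients=prepared.values,
            indices=np.arange(len(prepared)),
            source_length=source_length,
            padded_length=len(prepared),
            fingerprint=settings.fingerprint,
        )
    coefs = haar_transform(prepared)
    k = min(settings.wavelet_k, coefs.size)
    rep = retain_top_k(
        coefs, k, name=series.name, source_length=source_length,
        fingerprint=settings.fingerprint,
    )
    if settings.truncate_to is not None and settings.truncate_to < len(rep):
        rep = truncate_padding_bias(rep, settings.truncate_to)
    return rep
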