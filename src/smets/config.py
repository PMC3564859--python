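"""Pipeline settings shared by the representation and metric layers."""
from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineSettings", "DEFAULT_SETTINGS"]


@dataclass(frozen=True)
class PipelineSettings:
    """Everything needed to preprocess a series reproducibly.

    Attributes
    ----------
    normalize
        z-normalize each component (subtract mean, divide by population
        standard deviation) before any transform.
    wavelet_enabled
        Represent components by truncated Haar DWT coefficients. When off,
        distances are computed directly on the normalized, padded series.
    wavelet_k
        Number of largest-magnitude coefficients retained (clamped to the
        padded length). Default 16, the setting used for daily financial
        data padded to length 256.
    truncate_to
        Retained length after dropping trailing symbols affected by the
        zero padding; ``None`` disables. Default 15 (pairs with k=16).
    entropy_bins
        0 keeps exact value frequencies for the Shannon entropy of a
        component; a positive value quantizes onto that many uniform bins,
        useful for continuous data where exact frequencies degenerate to
        the uniform distribution.
    """

    normalize: bool = True
    wavelet_enabled: bool = True
    wavelet_k: int = 16
    truncate_to: int | None = 15
    entropy_bins: int = 0

    def __post_init__(self) -> None:
        if self.wavelet_k < 1:
            raise ValueError("wavelet_k must be >= 1")
        if self.truncate_to is not None and self.truncate_to < 1:
            raise ValueError("truncate_to must be >= 1 or None")
        if self.entropy_bins < 0:
            raise ValueError("entropy_bins must be >= 0")

    # fingerprint stamped onto representations so that distances between
    # incompatibly preprocessed series can be refused
    @property
    def fingerprint(self) -> tuple:
        return (self.normalize, self.wavelet_enabled, self.wavelet_k, self.truncate_to)

    def to_mapping(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineSettings":
        """Build settings from a flat or nested (wavelet:/entropy:) mapping."""
        flat: dict[str, Any] = {}
        for key, value in mapping.items():
            if key == "wavelet" and isinstance(value, Mapping):
                if "enabled" in value:
                    flat["wavelet_enabled"] = bool(value["enabled"])
                if "k" in value:
                    flat["wavelet_k"] = int(value["k"])
                if "truncate_to" in value:
                    t = value["truncate_to"]
                    flat["truncate_to"] = None if t is None else int(t)
            elif key == "entropy" and isinstance(value, Mapping):
                if "bins" in value:
                    flat["entropy_bins"] = int(value["bins"])
            elif key in cls.__dataclass_fields__:
                flat[key] = value
            else:
                raise KeyError(f"unknown settings key {key!r}")
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineSettings":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data)

    def replace(self, **kwargs: Any) -> "PipelineSettings":
        return replace(self, **kwargs)


DEFAULT_SETTINGS = PipelineSettings()
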