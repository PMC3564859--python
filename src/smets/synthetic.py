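"""Synthetic toy models: the dynamical behaviours the metric is meant to
tell apart, generated deterministically.

Three component archetypes cover the illustrative systems: sinusoids
(sustained or damped oscillations), exponential relaxations (monotonic
approach to a baseline), and constant traces (zero-information components).
Component shapes are a deterministic function of the spec parameters; the
seed only feeds observation noise and the stock-like random walks, so two
specs sharing oscillator settings produce bit-identical oscillators.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np

from .series import MultivariateSeries, UnivariateSeries

__all__ = [
    "ToyModelSpec",
    "generate_toy_model",
    "similar_models_trio",
    "random_walk_model",
    "random_model",
]


@dataclass(frozen=True)
class ToyModelSpec:
    """Recipe for one synthetic multivariate model.

    ``period`` and ``decay_rate`` are in samples and 1/samples; a zero
    decay rate gives sustained oscillation. ``noise`` is the standard
    deviation of i.i.d. Gaussian observation noise added to every
    component (default 0: noiseless archetypes).
    """

    name: str = "model"
    n_oscillating: int = 1
    n_monotonic: int = 0
    n_constant: int = 2
    length: int = 100
    period: float = 20.0
    amplitude: float = 1.0
    phase: float = 0.0
    decay_rate: float = 0.0
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_oscillating < 0 or self.n_monotonic < 0 or self.n_constant < 0:
            raise ValueError("component counts must be non-negative")
        if self.n_oscillating + self.n_monotonic + self.n_constant < 1:
            raise ValueError("need at least one component")
        if self.length < 4:
            raise ValueError("length must be >= 4")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any], name: str | None = None) -> "ToyModelSpec":
        kwargs = dict(mapping)
        if name is not None:
            kwargs["name"] = name
        return cls(**kwargs)


def generate_toy_model(spec: ToyModelSpec) -> MultivariateSeries:
    """Materialize a spec into a multivariate series (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.length, dtype=float)
    comps: list[UnivariateSeries] = []
    envelope = np.exp(-spec.decay_rate * t)
    for i in range(spec.n_oscillating):
        # phases evenly spread so oscillators within one model differ,
        # while identical settings give identical oscillators across models
        phase_i = spec.phase + 2.0 * np.pi * i / max(spec.n_oscillating, 1)
        values = spec.amplitude * envelope * np.sin(2.0 * np.pi * t / spec.period + phase_i)
        comps.append(UnivariateSeries(f"osc{i + 1}", values))
    for i in range(spec.n_monotonic):
        tau = spec.length / (3.0 + i)  # staggered relaxation times
        values = spec.amplitude * (1.0 + 0.5 * i) * np.exp(-t / tau)
        comps.append(UnivariateSeries(f"mono{i + 1}", values))
    for i in range(spec.n_constant):
        comps.append(UnivariateSeries(f"const{i + 1}", np.full(spec.length, 1.0 + 0.5 * i)))
    if spec.noise > 0:
        comps = [
            UnivariateSeries(c.name, c.values + rng.normal(scale=spec.noise, size=spec.length))
            for c in comps
        ]
    return MultivariateSeries(spec.name, tuple(comps))


def similar_models_trio(
    length: int = 100,
    period: float = 20.0,
    amplitude: float = 1.0,
    seed: int = 0,
) -> tuple[MultivariateSeries, MultivariateSeries, MultivariateSeries]:
    """Three deliberately confusable models: A, B, C.

    Each contains the *same* sustained oscillator plus 2, 4 and 9 constant
    components respectively (dimensions 3, 5, 10). Every pair matches
    perfectly on everything the matching can see and differs only in how
    many flat, zero-entropy components are left over — the configuration
    that isolates the dimension penalty, giving pairwise distances
    (m-n)/(m+n): A-B 1/4, B-C 1/3, A-C 7/13.
    """
    common = dict(length=length, period=period, amplitude=amplitude, seed=seed)
    a = generate_toy_model(ToyModelSpec(name="A", n_oscillating=1, n_constant=2, **common))
    b = generate_toy_model(ToyModelSpec(name="B", n_oscillating=1, n_constant=4, **common))
    c = generate_toy_model(ToyModelSpec(name="C", n_oscillating=1, n_constant=9, **common))
    return a, b, c


def random_walk_model(
    name: str, dimension: int, length: int, seed: int, drift: float = 0.0
) -> MultivariateSeries:
    """Stock-like model: each component an independent Gaussian random walk."""
    if dimension < 1 or length < 2:
        raise ValueError("need dimension >= 1 and length >= 2")
    rng = np.random.default_rng(seed)
    comps = tuple(
        UnivariateSeries(
            f"walk{i + 1}", np.cumsum(rng.normal(loc=drift, size=length))
        )
        for i in range(dimension)
    )
    return MultivariateSeries(name, comps)


def random_model(
    rng: np.random.Generator, dimension: int, length: int, name: str = "random"
) -> MultivariateSeries:
    """Heterogeneous random model mixing sinusoid, relaxation and walk shapes.

    Intended for randomized property suites: components have distinct
    shapes and continuous values, so cross-distances are almost surely
    tie-free.
    """
    t = np.arange(length, dtype=float)
    comps = []
    for i in range(dimension):
        kind = rng.integers(3)
        if kind == 0:
            values = rng.uniform(0.5, 2.0) * np.sin(
                2.0 * np.pi * t / rng.uniform(length / 8, length / 2)
                + rng.uniform(0, 2 * np.pi)
            )
        elif kind == 1:
            values = rng.uniform(0.5, 2.0) * np.exp(-t / rng.uniform(length / 6, length))
        else:
            values = np.cumsum(rng.normal(size=length)) / np.sqrt(length)
        values = values + 0.05 * rng.normal(size=length)
        comps.append(UnivariateSeries(f"c{i + 1}", values))
    return MultivariateSeries(name, tuple(comps))
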