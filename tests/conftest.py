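import numpy as np
import pytest

from smets import MultivariateSeries, UnivariateSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def uv(values, name="x"):
    return UnivariateSeries(name, np.asarray(values, dtype=float))


def mv(name, *components):
    return MultivariateSeries(name, tuple(components))
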