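import numpy as np
import pytest

from sisevol import ParameterSet
from sisevol.tradeoffs import tradeoff_model


@pytest.fixture(scope="session")
def table_defaults() -> ParameterSet:
    """Default parameter set: b=1, q=0.01, d0=0.25, gamma0=2, beta=0.2,
    alpha=0.75, phi0=1."""
    return ParameterSet()


@pytest.fixture(scope="session")
def models():
    return {kind: tradeoff_model(kind) for kind in ("i", "ii", "iii")}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
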