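import numpy as np
import pytest

from popdiff.synth import CohortSpec, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A deterministic 6-cell session with the full 12 x 10 trial structure."""
    spec = CohortSpec(n_cells_range=(6, 6), effect_delta=0.0)
    return generate_session(spec, "L2/3", "AL", seed=42)


@pytest.fixture(scope="session")
def effect_session():
    """A responsive-population session with the calibrated category effect."""
    spec = CohortSpec(n_cells_range=(12, 12))
    return generate_session(spec, "L2/3", "AM", seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
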