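import numpy as np
import pytest

from arterymorph.synthgen import PhantomSpec, make_artery_phantom


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec(
        inner_radius_um=50.0, layer_thicknesses_um=(5.0, 30.0, 15.0), seed=3
    )


@pytest.fixture(scope="session")
def phantom(default_spec):
    """One rendered phantom shared across read-only tests."""
    return make_artery_phantom(default_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
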