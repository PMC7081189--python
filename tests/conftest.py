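import math

import pytest

from pcflow.simulate import PhantomParams, make_phantom


@pytest.fixture(scope="session")
def noise_free_phantom():
    """Noise- and background-free phantom: flow recovery must be exact."""
    params = PhantomParams(
        seed=0, background_order=0, background_coeffs=(0.0,), snr_tissue=math.inf
    )
    return make_phantom(params)


@pytest.fixture(scope="session")
def default_phantom():
    """Default-noise phantom with a known linear background."""
    params = PhantomParams(
        seed=7, background_order=1, background_coeffs=(0.8, 0.5, -0.3)
    )
    return make_phantom(params)


@pytest.fixture(scope="session")
def clean_linear_phantom():
    """Noise-free phantom with a known linear background (bias-law oracle)."""
    params = PhantomParams(
        seed=3,
        background_order=1,
        background_coeffs=(0.0, 0.5, 0.0),
        snr_tissue=math.inf,
    )
    return make_phantom(params)
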