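import numpy as np
import pytest

from stentmorph import PhantomSpec, make_stent_mask


@pytest.fixture(scope="session")
def clean_sinusoid_spec() -> PhantomSpec:
    """Noise-free, pigtail-free sinusoid tube used across modules."""
    return PhantomSpec(
        height_px=360,
        width_px=80,
        tube_radius_px=3,
        amplitude_px=15.0,
        wavelength_px=180.0,
        phase_rad=0.0,
        pigtail_radius_px=0,
        noise_prob=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def clean_sinusoid(clean_sinusoid_spec):
    return make_stent_mask(clean_sinusoid_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
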