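import numpy as np
import pytest

from junctension import DiscAnnotation, build_mask
from junctension.synthetic import SynthDiscParams, generate_disc


@pytest.fixture(scope="session")
def noiseless_disc():
    """Noiseless two-compartment disc with posterior fold-change 1.5."""
    params = SynthDiscParams(posterior_multiplier=1.5, noise_sd_frac=0.0, seed=42)
    return generate_disc(params)


@pytest.fixture(scope="session")
def noiseless_annotation(noiseless_disc):
    return DiscAnnotation(
        center_px=noiseless_disc.center_px,
        posterior_side=noiseless_disc.posterior_axis,
        block_size_um=3.0,
    )


@pytest.fixture(scope="session")
def noiseless_mask(noiseless_disc):
    return build_mask(noiseless_disc.image)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
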