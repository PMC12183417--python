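import numpy as np
import pytest

import cobraki as ck
from cobraki.simkit import make_texture_phantom


@pytest.fixture(scope="session")
def oracle_dataset():
    """Noiseless flat-spectrum object with exactly bandlimited coils.

    In this regime an exact linear k-space interpolation kernel exists
    (coil spectra confined to a 2x2 box, well within the GRAPPA kernel),
    so closed-form GRAPPA is an exact oracle for every model family.
    """
    phantom = make_texture_phantom((64, 64), seed=5)
    coils = ck.make_coil_maps(
        4, (64, 64), mode="bandlimited", kspace_support=(2, 2), seed=3
    )
    spec = ck.AcquisitionSpec(
        echo_times=(3.2,), noise_sigma=0.0, matrix=(64, 64), n_coils=4, seed=0
    )
    full = ck.simulate_acquisition(phantom, coils, spec)[0]
    return phantom, coils, full


@pytest.fixture(scope="session")
def smooth_dataset():
    """Smooth-coil ellipse phantom acquisition with mild noise."""
    phantom = ck.make_phantom((64, 64), 5, seed=11)
    coils = ck.make_coil_maps(8, (64, 64), mode="smooth", seed=12)
    spec = ck.AcquisitionSpec(
        echo_times=(3.2,), noise_sigma=1e-3, matrix=(64, 64), n_coils=8, seed=13
    )
    full = ck.simulate_acquisition(phantom, coils, spec)[0]
    return phantom, coils, full


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
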