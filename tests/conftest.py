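"""Shared fixtures: canonical simulated spectra used across the suite."""

import numpy as np
import pytest

import cwesr as cw

CENTER = 3350.0


@pytest.fixture(scope="session")
def triplet_params():
    return cw.IsotropicTripletParams(a_N_G=15.0, W0_G=1.5)


@pytest.fixture(scope="session")
def triplet(triplet_params):
    """Noiseless symmetric fast-motion triplet."""
    axis = cw.field_axis(CENTER, triplet_params.a_N_G + 10 * triplet_params.W0_G + 2, 0.02)
    return cw.simulate_isotropic_triplet(triplet_params, axis)


@pytest.fixture(scope="session")
def powder_params():
    return cw.AxialPowderParams(A_par_G=32.0, A_perp_G=6.0, intrinsic_width_G=0.5)


@pytest.fixture(scope="session")
def powder(powder_params):
    """Rigid-limit-like ordered axial spectrum."""
    axis = cw.field_axis(
        CENTER, powder_params.A_par_G + 10 * powder_params.intrinsic_width_G + 2, 0.02
    )
    return cw.simulate_axial_powder(powder_params, axis)


@pytest.fixture(scope="session")
def mixture_components():
    """Mobile triplet + immobilized broad powder on a shared axis."""
    mobile = cw.IsotropicTripletParams(a_N_G=15.1, W0_G=1.5)
    immob = cw.AxialPowderParams(A_par_G=30.0, A_perp_G=8.0, intrinsic_width_G=2.0)
    axis = cw.field_axis(CENTER, 52.0, 0.02)
    return {
        "mobile": mobile,
        "immobilized": immob,
        "axis": axis,
        "basis_mobile": cw.simulate_isotropic_triplet(mobile, axis),
        "basis_immobilized": cw.simulate_axial_powder(immob, axis),
    }


def add_noise(spectrum, snr, seed):
    """Seeded Gaussian noise at a stated signal-to-noise ratio."""
    sigma = cw.noise_sigma_for_snr(spectrum, snr)
    rng = np.random.default_rng(seed)
    return spectrum.with_intensity(
        spectrum.intensity + rng.normal(0.0, sigma, spectrum.n)
    )
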