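import numpy as np
import pytest

from porequal import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """A modest noiseless phantom with 8 pores, shared across tests."""
    spec = PhantomSpec(
        grid_shape=(120, 120, 120),
        n_closed_pores=8,
        pore_radius_range=(9.0, 11.0),
        blur_sigma=2.0,
        noise_sigma=0.0,
        seed=42,
    )
    volume, gt = generate_phantom(spec)
    return spec, volume, gt


@pytest.fixture(scope="session")
def noisy_phantom():
    """Noisy counterpart (true SNR 10) used by pipeline-level tests."""
    spec = PhantomSpec(
        grid_shape=(140, 140, 140),
        n_closed_pores=10,
        pore_radius_range=(9.0, 11.0),
        blur_sigma=2.0,
        noise_sigma=10.0,
        seed=7,
    )
    volume, gt = generate_phantom(spec)
    return spec, volume, gt
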