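import numpy as np
import pytest

from mprheo import (
    OpticalConfig,
    TrapParameters,
    render_zscan,
    simulate_trajectory,
)

FRAME_RATE = 67.0


@pytest.fixture(scope="session")
def water_params() -> TrapParameters:
    """Trap/fluid parameters of a water-like measurement: anisotropic trap,
    fluid viscosity equal to the solvent viscosity."""
    return TrapParameters(kappa_x=1e-7, kappa_y=1e-7, kappa_z=4e-8)


@pytest.fixture(scope="session")
def long_traj(water_params):
    """A 1e5-frame equilibrium trajectory shared across estimator tests."""
    return simulate_trajectory(water_params, FRAME_RATE, 100_000, seed=42)


@pytest.fixture(scope="session")
def noise_free_config() -> OpticalConfig:
    return OpticalConfig(noise_model="none")


@pytest.fixture(scope="session")
def noisy_config() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def zscan_nf(noise_free_config):
    """Noise-free calibration scan: +/-2 um in 50 nm steps, with stage log."""
    stage_z = np.arange(-2.0, 2.0 + 1e-9, 0.05)
    frames = render_zscan(stage_z, noise_free_config)
    return stage_z, frames
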