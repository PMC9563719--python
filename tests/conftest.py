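import numpy as np
import pytest

from starchspec import SimConfig, VarietySpec


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_sim_config():
    """Scaled-down generator settings for fast pipeline tests: two varieties,
    18 samples, 48x48 cubes with a 32x32 ROI and a 120-band grid."""
    return SimConfig(
        varieties=[
            VarietySpec("A", 9, 10.0, 3.0, 2.0, 19.0),
            VarietySpec("B", 9, 19.0, 1.3, 17.0, 23.0),
        ],
        cube_rows=48,
        cube_cols=48,
        roi_size=32,
        n_bands=120,
    )


@pytest.fixture
def quiet_sim_config():
    """Noise-free, scatter-free settings: the spectrum is a deterministic
    function of starch and every cube pixel is identical."""
    return SimConfig(
        varieties=[VarietySpec("A", 4, 10.0, 3.0, 2.0, 19.0)],
        cube_rows=16,
        cube_cols=16,
        roi_size=8,
        n_bands=64,
        spectral_noise_sd=0.0,
        scatter_slope_sd=0.0,
        scatter_offset_sd=0.0,
        texture_amplitude=0.0,
        texture_chem_amplitude=0.0,
        pixel_noise_sd=0.0,
    )
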