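import numpy as np
import pytest

from stratiforest import LandscapeConfig, simulate_landscape


@pytest.fixture(scope="session")
def small_landscape():
    """A 400 x 400 m heterogeneous landscape shared across tests."""
    cfg = LandscapeConfig(
        extent_m=(400.0, 400.0),
        cell_size_m=20.0,
        spatial_corr_range_m=120.0,
        seed=11,
        chm_pixel_m=2.0,
        image_pixel_m=2.0,
        dem_pixel_m=4.0,
    )
    return simulate_landscape(cfg)


@pytest.fixture(scope="session")
def hetero_landscape():
    """Strongly structured landscape for design-comparison tests."""
    cfg = LandscapeConfig(
        extent_m=(800.0, 800.0),
        cell_size_m=20.0,
        spatial_corr_range_m=300.0,
        ba_mean=40.0,
        ba_sd=25.0,
        tph_mean=300.0,
        tph_sd=120.0,
        seed=5,
        chm_pixel_m=4.0,
        image_pixel_m=4.0,
    )
    return simulate_landscape(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
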