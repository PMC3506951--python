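import numpy as np
import pytest

from phscreen.synthetic_data import (
    PlantedStrain,
    SyntheticConfig,
    default_calibration,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def true_curve():
    return default_calibration()


@pytest.fixture
def quiet_config():
    """Synthetic conditions with every noise source switched off."""
    return SyntheticConfig(
        wt_ph_sd=0.0, ph_noise_sd=0.0, od_sd=0.0, fluor_cv=0.0,
        background_sd=0.0,
    )


@pytest.fixture
def small_screen_config():
    """One small plate with planted hits in both directions, default noise."""
    planted = (
        [PlantedStrain(f"low{i:02d}", ph_offset=-0.15) for i in range(5)]
        + [PlantedStrain(f"high{i:02d}", ph_offset=0.15) for i in range(5)]
    )
    return SyntheticConfig(
        n_plates=1, wells_per_plate=48, n_blank_per_plate=2,
        n_wt_per_plate=8, duration_h=12.0, planted=planted,
    )
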