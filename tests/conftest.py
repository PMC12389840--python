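import warnings

import numpy as np
import pytest

from radarhr import (RadarConfig, VitalParams, gen_radar_cube, range_fft,
                     remove_static_clutter, phase_matrix)
from radarhr.rangeproc import RangeMatrix


@pytest.fixture(scope="session")
def radar_config():
    return RadarConfig()


@pytest.fixture(scope="session")
def clean_params():
    """A noiseless, clutter-free, single-scatterer subject."""
    return VitalParams(seed=0, channel_noise_std=0.0,
                       channel_distortion_std=0.0, scatterer_jitter_m=0.0,
                       clutter_amplitude=0.0, second_scatterer_amplitude=0.0,
                       channel_motion_scale=(1.0, 1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def default_phase_matrix(radar_config):
    """Clutter-removed unwrapped phase of one default 520-frame cube."""
    cube = gen_radar_cube(radar_config, VitalParams(seed=3), 520)
    rm = range_fft(cube)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sub = remove_static_clutter(
            RangeMatrix(rm.values, rm.bin_spacing, rm.frame_rate))
    return phase_matrix(sub)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def rng(seed=0):
    return np.random.default_rng(seed)
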