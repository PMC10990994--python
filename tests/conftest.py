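import numpy as np
import pytest

from gazekit import GazeRecording, GridSpec, GridSimConfig, InfantSimConfig


@pytest.fixture
def grid():
    return GridSpec()


@pytest.fixture
def clean_grid_cfg():
    """Distortion-free, noise-free grid simulation settings."""
    return GridSimConfig(
        gain_x=1.0,
        gain_y=1.0,
        offset_x=0.0,
        offset_y=0.0,
        noise_sd_x=0.0,
        noise_sd_y=0.0,
        blink_rate=0.0,
        p_missing=0.0,
        seed=0,
    )


@pytest.fixture
def noise_free_infant_cfg():
    """Infant simulation with every noise source disabled."""
    return InfantSimConfig(noise_sd=0.0, timestamp_jitter_sd=0.0, seed=0)


def make_recording(x, y=None, rate=30.0, valid=None):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    valid = np.ones(len(x), dtype=bool) if valid is None else np.asarray(valid, bool)
    return GazeRecording(
        t=np.arange(len(x)) / rate,
        x=x,
        y=y,
        valid=valid,
        nominal_rate=rate,
    )
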