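import numpy as np
import pytest

from ftcdlat.epochs import Epoch, EpochSpec
from ftcdlat.recording import Recording, TRIAL_START
from ftcdlat.simulate import SimulationParams, simulate_session


@pytest.fixture
def spec():
    return EpochSpec()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epoch(left, right, fs=25.0, trial_index=1, cue_offset=12.0, **kw):
    left = np.asarray(left, dtype=float)
    t = np.arange(left.size) / fs - cue_offset
    return Epoch(trial_index=trial_index, fs=fs, t=t, left=left,
                 right=np.asarray(right, dtype=float), **kw)


@pytest.fixture
def epoch_factory():
    return make_epoch


def pulsatile_epoch(fs=25.0, n=750, level=100.0, pulse_amp=5.0,
                    pulse_hz=1.5, seed=0):
    """Clean pulsatile epoch around a constant level."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = level + pulse_amp * np.sin(2 * np.pi * pulse_hz * t)
    left = x + rng.normal(0, 0.1, n)
    right = x + rng.normal(0, 0.1, n)
    return make_epoch(left, right, fs=fs)


@pytest.fixture
def pulsatile_epoch_factory():
    return pulsatile_epoch


def clean_session_params(**overrides):
    """Artifact-free low-noise session at the analysis rate (fast)."""
    defaults = dict(seed=0, fs_raw=25.0, p_dropout_trial=0.0,
                    p_spike_trial=0.0)
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture
def clean_session_factory():
    def factory(**overrides):
        rec, gt = simulate_session(clean_session_params(**overrides))
        return rec, gt
    return factory


@pytest.fixture
def tiny_recording():
    return Recording(
        subject_id="s1", fs=100.0,
        left=np.array([1.0, 2.0, 3.0, 4.0]),
        right=np.array([4.0, 3.0, 2.0, 1.0]),
        markers=[(0, TRIAL_START), (2, TRIAL_START)],
    )
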