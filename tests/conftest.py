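"""Shared fixtures: small synthetic sessions and epoch-set builders."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.signal

from gonogo_erp import synthetic as syn
from gonogo_erp.montage import CHANNELS
from gonogo_erp.preprocess import EpochSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def icd_profile(rng):
    return syn.default_profile("sub-ICD01", "ICD", rng, attenuation_slope=-0.02)


@pytest.fixture
def hc_profile(rng):
    return syn.default_profile("sub-HC01", "HC", rng, attenuation_slope=-0.02)


@pytest.fixture
def default_session_events():
    """One full session under the default 3 x 80 trial protocol."""
    return syn.generate_trial_sequence(3, 80, 0.70, (0.5, 1.5), 0.5, seed=7)


@pytest.fixture
def annotated_small_session(icd_profile):
    """A short (1 x 40) annotated session plus its recording."""
    events = syn.generate_trial_sequence(1, 40, 0.70, (0.5, 1.5), 0.5, seed=3)
    events = syn.simulate_behavior(events, icd_profile, 1, seed=4)
    config = syn.CohortConfig()
    recording = syn.simulate_recording(events, icd_profile, 1, config, seed=5)
    return events, recording, config


def make_epochset(
    data: np.ndarray,
    fs_hz: float = 250.0,
    conditions=None,
    units: str = "microvolt",
) -> EpochSet:
    """Wrap a trials x 8 x samples array as a fully-retained EpochSet."""
    n_tr, n_ch, n_t = data.shape
    assert n_ch == len(CHANNELS)
    if conditions is None:
        conditions = np.array(["NoGo"] * n_tr, dtype=object)
    times = (np.arange(n_t) - int(0.2 * fs_hz)) / fs_hz * 1000.0
    return EpochSet(
        subject_id="sub-test",
        session=1,
        data=np.asarray(data, dtype=float),
        times_ms=times,
        conditions=np.asarray(conditions, dtype=object),
        channel_labels=list(CHANNELS),
        fs_hz=fs_hz,
        retained=np.ones(n_tr, dtype=bool),
        rejection_reason=np.array(["none"] * n_tr, dtype=object),
        units=units,
    )


def bandlimited_noise_epochs(
    rng: np.random.Generator,
    n_trials: int,
    n_times: int = 300,
    rms_uv: float = 10.0,
    fs_hz: float = 250.0,
) -> np.ndarray:
    """1-30 Hz pink-noise epochs, the texture real preprocessing produces."""
    sos = scipy.signal.butter(4, [1.0, 30.0], btype="band", fs=fs_hz, output="sos")
    out = np.empty((n_trials, len(CHANNELS), n_times))
    for i in range(n_trials):
        for c in range(len(CHANNELS)):
            raw = syn.pink_noise(2 * n_times, fs_hz, 1.0, rms_uv, rng)
            out[i, c] = scipy.signal.sosfilt(sos, raw)[n_times // 2:n_times // 2 + n_times]
    return out
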