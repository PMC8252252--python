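"""From a continuous recording to a clean stimulus-locked epoch set.

The stages mirror the standard ERP workflow for this task, in order:

1. zero-phase 1–30 Hz band-pass filtering;
2. segmentation into −200…1000 ms epochs with pre-stimulus baseline
   subtraction (edge events that do not fit are flagged, not extracted);
3. rejection of artifactual epochs whose per-channel excess kurtosis,
   z-scored across epochs, exceeds a threshold of 4;
4. rejection of epochs with erroneous behavior (SE: missed Go press;
   CE: press on NoGo);
5. extended-infomax ICA decomposition of the retained epochs with
   automatic flagging and removal of ocular components;
6. the participant-retention rule: a subject-session retaining fewer
   than 80% of its epochs is excluded from group analysis.

Rejection is monotone — a stage can only shrink the retained set and a
rejection reason, once assigned, is never overwritten.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .events import TrialEvent
from .montage import CENTRAL_CHANNELS, FRONTAL_CHANNELS, channel_indices
from .recording import Recording

REASON_NONE = "none"
REASON_EDGE = "edge"
REASON_KURTOSIS = "kurtosis"
REASON_BEHAVIOR = "behavior"
REASON_BASELINE = "baseline"
REASONS = (REASON_NONE, REASON_EDGE, REASON_KURTOSIS, REASON_BEHAVIOR, REASON_BASELINE)

UNITS_UV = "microvolt"
UNITS_Z = "zscore"


class ConvergenceError(RuntimeError):
    pass


@dataclass
class OcularRemovalReport:
    """Which ICA components were removed and why."""

    flagged: list[int]
    frontal_ratio: np.ndarray  # per component
    low_freq_fraction: np.ndarray  # per component
    n_iterations: int


@dataclass
class EpochSet:
    """Stimulus-locked epoch tensor with retention bookkeeping.

    ``data`` is trials x channels x samples; ``times_ms`` runs from the
    window start (−200 ms) in steps of ``1000 / fs_hz``.  ``retained``
    and ``rejection_reason`` always have one entry per trial, and
    ``rejection_reason != "none"`` iff the trial is not retained.
    """

    subject_id: str
    session: int
    data: np.ndarray
    times_ms: np.ndarray
    conditions: np.ndarray
    channel_labels: list[str]
    fs_hz: float
    retained: np.ndarray
    rejection_reason: np.ndarray
    units: str = UNITS_UV
    events: Optional[list[TrialEvent]] = None
    ica_report: Optional[OcularRemovalReport] = None

    def __post_init__(self) -> None:
        n = self.data.shape[0]
        if not (len(self.retained) == len(self.rejection_reason) == len(self.conditions) == n):
            raise ValueError("mask, reason and condition vectors must match the trial count")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel axis does not match channel_labels")
        mismatch = (self.rejection_reason != REASON_NONE) != ~self.retained
        if np.any(mismatch):
            raise ValueError("rejection_reason must be 'none' exactly for retained epochs")
        if self.units not in (UNITS_UV, UNITS_Z):
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.times_ms < 0

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            retained=self.retained.copy(),
            rejection_reason=self.rejection_reason.copy(),
        )

    def reject(self, indices: np.ndarray | Sequence[int], reason: str) -> None:
        """Mark trials as rejected; never overwrites an earlier reason."""
        if reason not in REASONS:
            raise ValueError(f"unknown rejection reason {reason!r}")
        for idx in np.atleast_1d(np.asarray(indices, dtype=int)):
            if self.retained[idx]:
                self.retained[idx] = False
                self.rejection_reason[idx] = reason

    def rejection_log(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(self.n_trials),
            "condition": self.conditions,
            "retained": self.retained,
            "reason": self.rejection_reason,
        })


@dataclass
class RetentionSummary:
    n_total: int
    n_retained: int
    fraction: float
    excluded: bool
    threshold: float


# ---------------------------------------------------------------------------
# filtering


def design_bandpass(low_hz: float, high_hz: float, fs_hz: float, order: int = 4) -> np.ndarray:
    """Butterworth band-pass in second-order sections."""
    if not 0 < low_hz < high_hz < fs_hz / 2:
        raise ValueError("band edges must satisfy 0 < low < high < fs/2")
    return scipy.signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")


def bandpass_filter(
    recording: Recording,
    low_hz: float = 1.0,
    high_hz: float = 30.0,
    order: int = 4,
) -> Recording:
    """Zero-phase (forward-backward) band-pass; protects peak latencies."""
    sos = design_bandpass(low_hz, high_hz, recording.fs_hz, order)
    # sosfiltfilt pads by 3 x (2*order+1) samples on each side
    padlen = 3 * (2 * sos.shape[0] + 1)
    if recording.n_samples <= padlen:
        raise ValueError(
            f"recording has {recording.n_samples} samples but zero-phase filtering "
            f"needs more than {padlen}; pad or record longer"
        )
    filtered = scipy.signal.sosfiltfilt(sos, recording.data, axis=1)
    return replace(recording, data=np.ascontiguousarray(filtered))


# ---------------------------------------------------------------------------
# epoching


def extract_epochs(
    recording: Recording,
    events: Sequence[TrialEvent],
    window_ms: tuple[float, float] = (-200.0, 1000.0),
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
) -> EpochSet:
    """Cut stimulus-locked epochs and subtract the pre-stimulus baseline.

    The sample window is half-open, ``[onset + window_ms[0], onset +
    window_ms[1])``, so 250 Hz with the default window yields exactly
    300 samples.  Events too close to the recording edges are flagged
    with reason ``"edge"`` and carry zeroed data.
    """
    events = list(events)
    if not events:
        raise ValueError("no events to epoch")
    fs = recording.fs_hz
    start_off = int(round(window_ms[0] / 1000.0 * fs))
    stop_off = int(round(window_ms[1] / 1000.0 * fs))
    n_times = stop_off - start_off
    times_ms = (np.arange(start_off, stop_off)) / fs * 1000.0

    n_trials = len(events)
    n_ch = recording.n_channels
    data = np.zeros((n_trials, n_ch, n_times))
    retained = np.ones(n_trials, dtype=bool)
    reasons = np.array([REASON_NONE] * n_trials, dtype=object)
    for i, ev in enumerate(events):
        onset = int(round(ev.onset_s * fs))
        lo, hi = onset + start_off, onset + stop_off
        if lo < 0 or hi > recording.n_samples:
            retained[i] = False
            reasons[i] = REASON_EDGE
            continue
        data[i] = recording.data[:, lo:hi]
    if not retained.any():
        raise ValueError("no events fall inside the recording bounds")

    baseline = (times_ms >= baseline_ms[0]) & (times_ms < baseline_ms[1])
    if not baseline.any():
        raise ValueError("baseline window contains no samples")
    data[retained] -= data[retained][:, :, baseline].mean(axis=2, keepdims=True)

    return EpochSet(
        subject_id=recording.subject_id,
        session=recording.session,
        data=data,
        times_ms=times_ms,
        conditions=np.array([ev.condition for ev in events], dtype=object),
        channel_labels=list(recording.channel_labels),
        fs_hz=fs,
        retained=retained,
        rejection_reason=reasons,
        units=UNITS_UV,
        events=events,
    )


# ---------------------------------------------------------------------------
# rejection


def reject_by_kurtosis(
    epochs: EpochSet,
    z_threshold: float = 4.0,
    mode: str = "zscore",
) -> EpochSet:
    """Reject artifact epochs by per-channel excess kurtosis.

    In the default ``"zscore"`` mode the excess kurtosis of each
    retained epoch's samples is standardized across epochs within each
    channel, and an epoch is rejected when any channel's z-scored value
    exceeds ``z_threshold``.  ``"raw"`` mode compares the excess
    kurtosis itself against the threshold.
    """
    if mode not in ("zscore", "raw"):
        raise ValueError("mode must be 'zscore' or 'raw'")
    out = epochs.copy()
    idx = np.flatnonzero(out.retained)
    if idx.size < 8:
        raise ValueError("need at least 8 retained epochs to estimate the kurtosis spread")
    k = scipy.stats.kurtosis(out.data[idx], axis=2, fisher=True, bias=True)  # (n_ret, n_ch)
    if mode == "raw":
        exceed = k > z_threshold
    else:
        mu = k.mean(axis=0)
        sd = k.std(axis=0, ddof=1)
        exceed = np.zeros_like(k, dtype=bool)
        for ch in range(k.shape[1]):
            if sd[ch] == 0:
                warnings.warn(
                    f"kurtosis values have zero variance on channel "
                    f"{out.channel_labels[ch]}; no rejection there",
                    stacklevel=2,
                )
                continue
            exceed[:, ch] = (k[:, ch] - mu[ch]) / sd[ch] > z_threshold
    out.reject(idx[exceed.any(axis=1)], REASON_KURTOSIS)
    return out


def reject_by_behavior(epochs: EpochSet, events: Optional[Sequence[TrialEvent]] = None) -> EpochSet:
    """Drop epochs whose trial carries a behavioral error (SE or CE)."""
    events = list(events) if events is not None else epochs.events
    if events is None:
        raise ValueError("no events available for behavioral rejection")
    if len(events) != epochs.n_trials:
        raise ValueError(
            f"{len(events)} events do not match {epochs.n_trials} epochs"
        )
    out = epochs.copy()
    bad = [i for i, ev in enumerate(events) if ev.is_error]
    out.reject(bad, REASON_BEHAVIOR)
    return out


# ---------------------------------------------------------------------------
# ICA ocular removal


def remove_ocular_components(
    epochs: EpochSet,
    frontal_ratio_threshold: float = 2.0,
    low_freq_fraction_threshold: float = 0.60,
    low_freq_cutoff_hz: float = 5.0,
    seed: int = 0,
    max_iter: int = 500,
    signal_band_high_hz: float = 30.0,
) -> EpochSet:
    """Remove eye-movement components by extended-infomax ICA.

    The retained epochs are concatenated and decomposed into as many
    components as channels.  A component is flagged as ocular when

    * its scalp pattern is frontal-dominant — mean absolute weight at
      F3/Fz/F4 exceeds ``frontal_ratio_threshold`` times the mean at
      C3/Cz/C4/CPz — and
    * more than ``low_freq_fraction_threshold`` of its source power
      lies below ``low_freq_cutoff_hz``.

    Flagged components are zeroed and the rest back-projected, so with
    nothing flagged the reconstruction equals the input.  The flagged
    indices and criterion values are attached as ``ica_report``.
    """
    import mne

    if epochs.units != UNITS_UV:
        raise ValueError("ICA must run on microvolt epochs, before z-standardization")
    out = epochs.copy()
    idx = np.flatnonzero(out.retained)
    if idx.size == 0:
        raise ValueError("no retained epochs for ICA")
    n_ch = len(out.channel_labels)
    n_times = out.data.shape[2]
    concat = out.data[idx].transpose(1, 0, 2).reshape(n_ch, -1)

    info = mne.create_info(out.channel_labels, sfreq=out.fs_hz, ch_types="eeg")
    raw = mne.io.RawArray(concat * 1e-6, info, verbose="error")
    # Fitting needs only ~20k samples for an 8-channel decomposition; the
    # unmixing is applied to the full-rate data afterwards.  Decimation
    # must keep the effective rate above twice the signal band, otherwise
    # aliasing Gaussianizes the sources and infomax stalls.
    max_decim = max(1, int(out.fs_hz // (2.0 * signal_band_high_hz)))
    decim = max(1, min(concat.shape[1] // 20_000, max_decim))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ica = mne.preprocessing.ICA(
            n_components=n_ch,
            method="infomax",
            fit_params=dict(extended=True),
            random_state=seed,
            max_iter=max_iter,
            verbose="error",
        )
        ica.fit(raw, decim=decim, verbose="error")
    n_iter = int(getattr(ica, "n_iter_", 0))
    # infomax anneals up to the iteration cap by design; a genuine failure
    # manifests as a non-finite unmixing matrix
    if not np.all(np.isfinite(ica.unmixing_matrix_)):
        raise ConvergenceError(
            f"extended-infomax ICA diverged after {n_iter} iterations; "
            f"try a different seed"
        )

    patterns = np.abs(ica.get_components())  # channels x components
    frontal = channel_indices(FRONTAL_CHANNELS)
    central = channel_indices(CENTRAL_CHANNELS)
    with np.errstate(divide="ignore"):
        ratio = patterns[frontal].mean(axis=0) / patterns[central].mean(axis=0)

    sources = ica.get_sources(raw).get_data()
    freqs, psd = scipy.signal.welch(sources, fs=out.fs_hz, nperseg=min(1024, sources.shape[1]))
    total = psd.sum(axis=1)
    low = psd[:, freqs < low_freq_cutoff_hz].sum(axis=1)
    low_fraction = np.divide(low, total, out=np.zeros_like(total), where=total > 0)

    flagged = [
        c for c in range(n_ch)
        if ratio[c] > frontal_ratio_threshold and low_fraction[c] > low_freq_fraction_threshold
    ]
    if flagged:
        cleaned = ica.apply(raw.copy(), exclude=flagged, verbose="error")
        restored = cleaned.get_data() * 1e6
    else:
        restored = concat
    out.data[idx] = restored.reshape(n_ch, idx.size, n_times).transpose(1, 0, 2)
    out.ica_report = OcularRemovalReport(
        flagged=flagged,
        frontal_ratio=ratio,
        low_freq_fraction=low_fraction,
        n_iterations=n_iter,
    )
    return out


# ---------------------------------------------------------------------------
# retention


def retention_summary(epochs: EpochSet, exclusion_threshold: float = 0.80) -> RetentionSummary:
    """Fraction of retained epochs and the participant-exclusion flag."""
    if epochs.n_trials == 0:
        raise ValueError("empty epoch set")
    fraction = epochs.n_retained / epochs.n_trials
    return RetentionSummary(
        n_total=epochs.n_trials,
        n_retained=epochs.n_retained,
        fraction=fraction,
        excluded=fraction < exclusion_threshold,
        threshold=exclusion_threshold,
    )
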