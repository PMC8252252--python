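"""ERP quantification: per-epoch z-standardization, condition averages,
N2/P3 peak scoring, and trial-smoothed ERP images.

N2 is scored as the minimal value in 200–500 ms post-stimulus and P3 as
the maximal value in 400–700 ms, on the condition-average waveform of
baseline-z-scored epochs.  The peak is the extremum *sample* (not a
mean amplitude); a window-edge extremum is accepted and ties break to
the earliest time, which makes scoring deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np

from .preprocess import REASON_BASELINE, UNITS_UV, UNITS_Z, EpochSet


@dataclass(frozen=True)
class ComponentSpec:
    """Search window and polarity of one ERP component."""

    name: str
    search_window_ms: tuple[float, float]
    polarity: str  # "negative" or "positive"

    def __post_init__(self) -> None:
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")
        lo, hi = self.search_window_ms
        if lo >= hi:
            raise ValueError("search window must be a nonempty interval")


N2 = ComponentSpec("N2", (200.0, 500.0), "negative")
P3 = ComponentSpec("P3", (400.0, 700.0), "positive")
DEFAULT_COMPONENTS = (N2, P3)


@dataclass
class ErpProfile:
    """Condition-average waveform per channel, in z-units."""

    condition: str
    times_ms: np.ndarray
    data: np.ndarray  # channels x samples
    channel_labels: list[str]
    n_trials_used: int
    units: str = UNITS_Z

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


@dataclass(frozen=True)
class PeakMeasure:
    component: str
    channel: str
    amplitude: float  # z-units (value of the waveform at the peak)
    latency_ms: float


def standardize_epochs(
    epochs: EpochSet,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
    pooled_channels: bool = False,
) -> EpochSet:
    """Baseline z-score each epoch: subtract the pre-stimulus mean and
    divide by the pre-stimulus standard deviation.

    By default the baseline statistics are per channel; with
    ``pooled_channels`` one SD pooled over channels is used per epoch.
    Epochs whose baseline variance is zero cannot be standardized and
    are excluded with reason ``"baseline"``.
    """
    if epochs.units != UNITS_UV:
        raise ValueError("standardize_epochs expects microvolt epochs")
    out = epochs.copy()
    mask = (out.times_ms >= baseline_ms[0]) & (out.times_ms < baseline_ms[1])
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    idx = np.flatnonzero(out.retained)
    base = out.data[idx][:, :, mask]
    mu = base.mean(axis=2, keepdims=True)
    if pooled_channels:
        sd = base.std(axis=(1, 2), ddof=0)[:, None, None] * np.ones((1, base.shape[1], 1))
    else:
        sd = base.std(axis=2, ddof=0, keepdims=True)
    degenerate = np.any(sd[..., 0] == 0, axis=1)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} epoch(s) have a constant baseline and were excluded",
            stacklevel=2,
        )
    good = idx[~degenerate]
    sel = ~degenerate
    out.data[good] = (out.data[good] - mu[sel]) / sd[sel]
    out.reject(idx[degenerate], REASON_BASELINE)
    out.units = UNITS_Z
    return out


def average_erp(epochs: EpochSet, condition: str, require_z: bool = True) -> ErpProfile:
    """Pointwise mean over retained epochs of one condition."""
    if require_z and epochs.units != UNITS_Z:
        raise ValueError("average_erp expects z-scored epochs (or pass require_z=False)")
    sel = epochs.retained & (epochs.conditions == condition)
    n = int(sel.sum())
    if n == 0:
        raise ValueError(f"no retained epochs of condition {condition!r}")
    return ErpProfile(
        condition=condition,
        times_ms=epochs.times_ms.copy(),
        data=epochs.data[sel].mean(axis=0),
        channel_labels=list(epochs.channel_labels),
        n_trials_used=n,
        units=epochs.units,
    )


def find_peak(profile: ErpProfile, channel: str, spec: ComponentSpec) -> PeakMeasure:
    """Extremum sample in the component's search window (ties: earliest).

    N2 (negative polarity) takes the minimum, P3 (positive) the maximum;
    window endpoints are inclusive.
    """
    lo, hi = spec.search_window_ms
    if lo < profile.times_ms[0] or hi > profile.times_ms[-1]:
        raise ValueError(
            f"search window {spec.search_window_ms} outside the epoch time axis "
            f"[{profile.times_ms[0]}, {profile.times_ms[-1]}]"
        )
    mask = (profile.times_ms >= lo) & (profile.times_ms <= hi)
    wave = profile.channel(channel)[mask]
    times = profile.times_ms[mask]
    i = int(np.argmin(wave)) if spec.polarity == "negative" else int(np.argmax(wave))
    # np.argmin/argmax return the first occurrence, i.e. the earliest time
    return PeakMeasure(
        component=spec.name,
        channel=channel,
        amplitude=float(wave[i]),
        latency_ms=float(times[i]),
    )


def peak_magnitude(measure: PeakMeasure, spec: ComponentSpec) -> float:
    """Peak amplitude rectified into the component's polarity direction.

    For N2 this is ``-amplitude`` (a strong N2 is a large magnitude);
    deterioration of either component is then a *decrease* in magnitude,
    which is the convention used for the ICD-score association.
    """
    return -measure.amplitude if spec.polarity == "negative" else measure.amplitude


def erp_image(
    epochs: EpochSet,
    channel: str,
    condition: str,
    smoothing_width: int = 10,
) -> np.ndarray:
    """Trials x time raster of retained single-trial epochs, smoothed by a
    centered moving average of ``smoothing_width`` neighboring trials
    (truncated at the raster edges).  Trial order is preserved.
    """
    if smoothing_width < 1:
        raise ValueError("smoothing_width must be >= 1")
    sel = epochs.retained & (epochs.conditions == condition)
    if not sel.any():
        raise ValueError(f"no retained epochs of condition {condition!r}")
    ch = epochs.channel_labels.index(channel)
    raster = epochs.data[sel, ch, :]
    if smoothing_width == 1:
        return raster.copy()
    n = raster.shape[0]
    half_lo = (smoothing_width - 1) // 2
    half_hi = smoothing_width // 2
    out = np.empty_like(raster)
    for i in range(n):
        lo = max(i - half_lo, 0)
        hi = min(i + half_hi + 1, n)
        out[i] = raster[lo:hi].mean(axis=0)
    return out
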