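"""Per-session analysis building blocks used by the pipeline.

``process_session`` runs the preprocessing chain on one recording;
``score_session`` turns a clean epoch set into NoGo N2/P3 peak measures;
``measure_cohort_peaks`` maps both over a cohort and returns the tidy
peak table the statistics stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import erp, preprocess
from .events import NOGO, TrialEvent
from .montage import CHANNELS
from .recording import Recording
from .synthetic import Cohort


@dataclass(frozen=True)
class PreprocessParams:
    band_low_hz: float = 1.0
    band_high_hz: float = 30.0
    filter_order: int = 4
    window_ms: tuple[float, float] = (-200.0, 1000.0)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    kurtosis_threshold: float = 4.0
    kurtosis_mode: str = "zscore"
    run_ica: bool = True
    ica_frontal_ratio: float = 2.0
    ica_low_freq_fraction: float = 0.60
    ica_seed: int = 0
    ica_max_iter: int = 200
    retention_threshold: float = 0.80


@dataclass
class SessionResult:
    epochs: preprocess.EpochSet  # z-scored, cleaned
    retention: preprocess.RetentionSummary
    peaks: list[erp.PeakMeasure] = field(default_factory=list)
    profiles: dict[str, erp.ErpProfile] = field(default_factory=dict)


def process_session(
    recording: Recording,
    events: Sequence[TrialEvent],
    params: PreprocessParams = PreprocessParams(),
) -> tuple[preprocess.EpochSet, preprocess.RetentionSummary]:
    """Filter, epoch, reject (kurtosis then behavior), remove ocular ICA
    components, and summarize retention.  Returns microvolt epochs."""
    filtered = preprocess.bandpass_filter(
        recording, params.band_low_hz, params.band_high_hz, params.filter_order
    )
    epochs = preprocess.extract_epochs(filtered, events, params.window_ms, params.baseline_ms)
    epochs = preprocess.reject_by_kurtosis(epochs, params.kurtosis_threshold, params.kurtosis_mode)
    epochs = preprocess.reject_by_behavior(epochs, events)
    if params.run_ica:
        epochs = preprocess.remove_ocular_components(
            epochs,
            frontal_ratio_threshold=params.ica_frontal_ratio,
            low_freq_fraction_threshold=params.ica_low_freq_fraction,
            seed=params.ica_seed,
            max_iter=params.ica_max_iter,
            signal_band_high_hz=params.band_high_hz,
        )
    summary = preprocess.retention_summary(epochs, params.retention_threshold)
    return epochs, summary


def score_session(
    epochs: preprocess.EpochSet,
    components: Sequence[erp.ComponentSpec] = erp.DEFAULT_COMPONENTS,
    channels: Sequence[str] = CHANNELS,
    condition: str = NOGO,
    baseline_ms: tuple[float, float] = (-200.0, 0.0),
) -> SessionResult:
    """Z-standardize, average the target condition, and score all peaks."""
    z = erp.standardize_epochs(epochs, baseline_ms)
    profile = erp.average_erp(z, condition)
    peaks = [
        erp.find_peak(profile, ch, spec) for spec in components for ch in channels
    ]
    result = SessionResult(
        epochs=z,
        retention=preprocess.retention_summary(z),
        peaks=peaks,
        profiles={condition: profile},
    )
    return result


def peaks_to_frame(
    peaks: Sequence[erp.PeakMeasure],
    subject: str,
    group: str,
    session: int,
) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "subject": subject,
            "group": group,
            "session": session,
            "component": p.component,
            "channel": p.channel,
            "amplitude_z": p.amplitude,
            "latency_ms": p.latency_ms,
        }
        for p in peaks
    ])


def behavior_summary(events: Sequence[TrialEvent]) -> dict:
    """Go RT mean/SD and SE/CE counts for one annotated session."""
    go_rts = [ev.rt_ms for ev in events if ev.condition == "Go" and ev.pressed]
    se = sum(ev.error_type == "SE" for ev in events)
    ce = sum(ev.error_type == "CE" for ev in events)
    return {
        "rt_mean_ms": float(np.mean(go_rts)) if go_rts else np.nan,
        "rt_sd_ms": float(np.std(go_rts, ddof=1)) if len(go_rts) > 1 else np.nan,
        "se_count": int(se),
        "ce_count": int(ce),
        "total_errors": int(se + ce),
    }


def measure_cohort_peaks(
    cohort: Cohort,
    params: PreprocessParams = PreprocessParams(),
    components: Sequence[erp.ComponentSpec] = erp.DEFAULT_COMPONENTS,
    channels: Sequence[str] = CHANNELS,
    collect_behavior: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run every subject-session through preprocessing and peak scoring.

    Returns ``(peaks, retention, behavior)`` data frames.  Subjects whose
    retention falls below the threshold in either session are flagged
    ``excluded`` in the retention table and omitted from the peak table,
    mirroring the participant-discard rule.
    """
    peak_rows: list[pd.DataFrame] = []
    retention_rows = []
    behavior_rows = []
    for sub in cohort.subjects:
        prof = sub.profile
        session_frames = []
        excluded = False
        for session in (1, 2):
            events, recording = sub.realize_session(session)
            epochs, summary = process_session(recording, events, params)
            retention_rows.append({
                "subject": prof.subject_id,
                "group": prof.group,
                "session": session,
                "n_total": summary.n_total,
                "n_retained": summary.n_retained,
                "fraction": summary.fraction,
                "excluded": summary.excluded,
            })
            if collect_behavior:
                behavior_rows.append({
                    "subject": prof.subject_id,
                    "group": prof.group,
                    "session": session,
                    **behavior_summary(events),
                })
            if summary.excluded:
                excluded = True
                continue
            scored = score_session(epochs, components, channels)
            session_frames.append(
                peaks_to_frame(scored.peaks, prof.subject_id, prof.group, session)
            )
        if not excluded and session_frames:
            peak_rows.extend(session_frames)
    peaks = (
        pd.concat(peak_rows, ignore_index=True)
        if peak_rows
        else pd.DataFrame(columns=["subject", "group", "session", "component",
                                   "channel", "amplitude_z", "latency_ms"])
    )
    return peaks, pd.DataFrame(retention_rows), pd.DataFrame(behavior_rows)


def peak_matrix(
    peaks: pd.DataFrame,
    component: str,
    session: int,
    group: Optional[str] = None,
    channels: Sequence[str] = CHANNELS,
    value: str = "amplitude_z",
) -> tuple[np.ndarray, list[str]]:
    """Subjects x channels matrix of one component/session (sorted ids)."""
    sel = peaks[(peaks.component == component) & (peaks.session == session)]
    if group is not None:
        sel = sel[sel.group == group]
    pivot = sel.pivot(index="subject", columns="channel", values=value)
    pivot = pivot.sort_index()[list(channels)]
    return pivot.to_numpy(), list(pivot.index)
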