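"""Readers and writers for the pipeline's interchange formats.

* continuous EEG: EDF (European Data Format, 16-bit) — written with a
  configurable physical range (default ±1000 µV), so the round-trip
  error per sample is bounded by half a quantization step;
* trial events: tab-separated tables following the BIDS events
  convention (onset / duration / trial_type / ...);
* cohorts: a JSON manifest listing subject id, group, QUIP-RS score and
  per-session file paths;
* results: peak tables as CSV and statistics as JSON.

All readers validate and reject malformed input rather than coercing
it; all writers are deterministic byte-wise for identical input.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .events import ERROR_TYPES, TrialEvent, validate_sequence
from .recording import Recording
from .synthetic import GROUPS

# symmetric digital range so 0 uV is exactly representable
EDF_DIGITAL_MIN = -32767
EDF_DIGITAL_MAX = 32767
DEFAULT_PHYSICAL_RANGE_UV = 1000.0

EVENT_COLUMNS = [
    "onset", "duration", "trial_type", "block", "pressed", "response_time", "error_type",
]

PEAK_COLUMNS = [
    "subject", "group", "session", "component", "channel", "amplitude_z", "latency_ms",
]


class FormatError(ValueError):
    """A file failed structural validation; the message names the field."""


# ---------------------------------------------------------------------------
# EDF


def _ascii_field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF field too long ({s!r} > {width} chars)")
    return s.ljust(width).encode("ascii")


def _num_field(value: float, width: int) -> bytes:
    for fmt in (f"{value:g}", f"{value:.{max(width - 7, 0)}f}", f"{int(round(value))}"):
        if len(fmt) <= width:
            return fmt.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} EDF chars")


def write_recording(
    recording: Recording,
    path: str | Path,
    physical_range_uv: float = DEFAULT_PHYSICAL_RANGE_UV,
) -> Path:
    """Write a recording as 16-bit EDF with 1-second data records.

    The final record is zero-padded to a whole second; the true sample
    count is kept in the header's reserved field so :func:`read_recording`
    restores the exact length.  Samples outside ±``physical_range_uv``
    are clipped.
    """
    path = Path(path)
    fs = recording.fs_hz
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = recording.n_channels
    n_samples = recording.n_samples
    n_records = max(math.ceil(n_samples / spr), 1)

    pmin, pmax = -physical_range_uv, physical_range_uv
    scale = (EDF_DIGITAL_MAX - EDF_DIGITAL_MIN) / (pmax - pmin)
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n_samples] = np.clip(recording.data, pmin, pmax)
    digital = np.round((padded - pmin) * scale + EDF_DIGITAL_MIN).astype("<i2")

    header_bytes = 256 + 256 * n_ch
    header = b"".join([
        _ascii_field("0", 8),
        _ascii_field(recording.subject_id, 80),
        _ascii_field(f"session={recording.session} ref={recording.reference_note[:60]}", 80),
        _ascii_field("01.01.00", 8),
        _ascii_field("00.00.00", 8),
        _ascii_field(str(header_bytes), 8),
        _ascii_field(f"NSAMP={n_samples}", 44),
        _ascii_field(str(n_records), 8),
        _ascii_field("1", 8),
        _ascii_field(str(n_ch), 4),
    ])
    per_signal = b"".join([
        b"".join(_ascii_field(lbl, 16) for lbl in recording.channel_labels),
        b"".join(_ascii_field("AgAgCl dry electrode", 80) for _ in range(n_ch)),
        b"".join(_ascii_field("uV", 8) for _ in range(n_ch)),
        b"".join(_num_field(pmin, 8) for _ in range(n_ch)),
        b"".join(_num_field(pmax, 8) for _ in range(n_ch)),
        b"".join(_num_field(EDF_DIGITAL_MIN, 8) for _ in range(n_ch)),
        b"".join(_num_field(EDF_DIGITAL_MAX, 8) for _ in range(n_ch)),
        b"".join(_ascii_field("", 80) for _ in range(n_ch)),
        b"".join(_num_field(spr, 8) for _ in range(n_ch)),
        b"".join(_ascii_field("", 32) for _ in range(n_ch)),
    ])
    # records: for each record, each signal's samples contiguously
    records = digital.reshape(n_ch, n_records, spr).transpose(1, 0, 2)
    path.write_bytes(header + per_signal + records.tobytes())
    return path


def _read_ascii(buf: bytes, offset: int, width: int, name: str) -> str:
    raw = buf[offset:offset + width]
    if len(raw) < width:
        raise FormatError(f"EDF truncated while reading header field {name!r}")
    try:
        return raw.decode("ascii").strip()
    except UnicodeDecodeError as exc:
        raise FormatError(f"EDF header field {name!r} is not ASCII") from exc


def _read_num(buf: bytes, offset: int, width: int, name: str) -> float:
    text = _read_ascii(buf, offset, width, name)
    try:
        return float(text)
    except ValueError as exc:
        raise FormatError(f"EDF header field {name!r} is not numeric: {text!r}") from exc


def read_recording(path: str | Path) -> Recording:
    """Read a 16-bit EDF file written by :func:`write_recording`.

    Also accepts generic single-rate EDF files; the exact-length
    restoration relies on the ``NSAMP=`` annotation when present.
    """
    path = Path(path)
    buf = path.read_bytes()
    if len(buf) < 256:
        raise FormatError("EDF file shorter than the 256-byte fixed header")
    subject_id = _read_ascii(buf, 8, 80, "patient identification")
    rec_field = _read_ascii(buf, 88, 80, "recording identification")
    header_bytes = int(_read_num(buf, 184, 8, "header bytes"))
    reserved = _read_ascii(buf, 192, 44, "reserved")
    n_records = int(_read_num(buf, 236, 8, "number of data records"))
    record_dur = _read_num(buf, 244, 8, "data record duration")
    n_ch = int(_read_num(buf, 252, 4, "number of signals"))
    if n_ch <= 0:
        raise FormatError("EDF header field 'number of signals' must be positive")
    if header_bytes != 256 + 256 * n_ch:
        raise FormatError("EDF header field 'header bytes' inconsistent with signal count")
    if record_dur <= 0:
        raise FormatError("EDF header field 'data record duration' must be positive")

    def signal_fields(base: int, width: int, name: str, numeric: bool = False):
        out = []
        for i in range(n_ch):
            off = 256 + base * n_ch + i * width
            out.append(
                _read_num(buf, off, width, f"{name}[{i}]")
                if numeric else _read_ascii(buf, off, width, f"{name}[{i}]")
            )
        return out

    labels = signal_fields(0, 16, "label")
    pmins = signal_fields(96 + 8, 8, "physical minimum", numeric=True)
    pmaxs = signal_fields(96 + 16, 8, "physical maximum", numeric=True)
    dmins = signal_fields(96 + 24, 8, "digital minimum", numeric=True)
    dmaxs = signal_fields(96 + 32, 8, "digital maximum", numeric=True)
    sprs = [int(v) for v in signal_fields(96 + 120, 8, "samples per record", numeric=True)]
    if len(set(sprs)) != 1:
        raise FormatError("EDF field 'samples per record' differs across signals")
    spr = sprs[0]
    fs = spr / record_dur

    expected = header_bytes + n_records * n_ch * spr * 2
    if len(buf) < expected:
        raise FormatError("EDF data section shorter than the header announces")
    digital = np.frombuffer(buf[header_bytes:expected], dtype="<i2")
    data = digital.reshape(n_records, n_ch, spr).transpose(1, 0, 2).reshape(n_ch, -1)

    out = np.empty(data.shape)
    for i in range(n_ch):
        if dmaxs[i] == dmins[i]:
            raise FormatError(f"EDF header field 'digital maximum[{i}]' equals the minimum")
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        out[i] = (data[i] - dmins[i]) * gain + pmins[i]

    if reserved.startswith("NSAMP="):
        try:
            n_true = int(reserved[len("NSAMP="):])
        except ValueError as exc:
            raise FormatError("EDF reserved field carries a malformed NSAMP annotation") from exc
        if not 0 < n_true <= out.shape[1]:
            raise FormatError("EDF NSAMP annotation exceeds the stored sample count")
        out = out[:, :n_true]

    session = 1
    ref_note = ""
    for token in rec_field.split():
        if token.startswith("session="):
            session = int(token.split("=", 1)[1])
        elif token.startswith("ref="):
            ref_note = rec_field.split("ref=", 1)[1]
            break
    return Recording(
        subject_id=subject_id, session=session, data=out,
        channel_labels=labels, fs_hz=fs, reference_note=ref_note,
    )


# ---------------------------------------------------------------------------
# events TSV


def write_events(
    events: Iterable[TrialEvent],
    path: str | Path,
    stimulus_duration_s: float | None = None,
) -> Path:
    """Write trial events as a BIDS-style tab-separated table."""
    path = Path(path)
    events = validate_sequence(events)
    rows = []
    for ev in events:
        rows.append({
            "onset": f"{ev.onset_s:.6f}",
            "duration": "n/a" if stimulus_duration_s is None else f"{stimulus_duration_s:.3f}",
            "trial_type": ev.condition,
            "block": ev.block_index,
            "pressed": "n/a" if ev.pressed is None else str(bool(ev.pressed)).lower(),
            "response_time": f"{ev.rt_ms:.3f}" if ev.rt_ms is not None else "n/a",
            "error_type": ev.error_type,
        })
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def read_events(path: str | Path) -> list[TrialEvent]:
    """Read a trial-event table, enforcing the behavioral invariants.

    A row whose error flag contradicts its condition/press combination
    (e.g. a commission error on a Go trial) is rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"events table is missing required column {col!r}")
    events: list[TrialEvent] = []
    for i, row in df.iterrows():
        pressed_raw = row["pressed"]
        pressed = None if pressed_raw == "n/a" else pressed_raw == "true"
        rt = None if row["response_time"] == "n/a" else float(row["response_time"])
        error = row["error_type"]
        if error not in ERROR_TYPES:
            raise FormatError(f"row {i}: unknown error_type {error!r}")
        try:
            events.append(TrialEvent(
                onset_s=float(row["onset"]),
                condition=row["trial_type"],
                block_index=int(row["block"]),
                pressed=pressed,
                rt_ms=rt,
                error_type=error,
            ))
        except ValueError as exc:
            raise FormatError(f"row {i}: {exc}") from exc
    return validate_sequence(events)


# ---------------------------------------------------------------------------
# cohort manifest


@dataclass
class ManifestEntry:
    subject_id: str
    group: str
    quip_rs: float
    sessions: dict[int, dict[str, str]]  # session -> {"eeg": path, "events": path}


@dataclass
class CohortManifest:
    seed: int
    entries: list[ManifestEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def write_cohort_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "seed": manifest.seed,
        "subjects": [
            {
                "subject_id": e.subject_id,
                "group": e.group,
                "quip_rs": e.quip_rs,
                "sessions": {str(s): files for s, files in sorted(e.sessions.items())},
            }
            for e in manifest.entries
        ],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_cohort_manifest(path: str | Path, lazy: bool = False) -> CohortManifest:
    """Read a cohort manifest; referenced files must exist unless *lazy*."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"manifest is not valid JSON: {exc}") from exc
    entries: list[ManifestEntry] = []
    seen: set[str] = set()
    for sub in payload.get("subjects", []):
        sid = sub["subject_id"]
        group = sub["group"]
        if group not in GROUPS:
            raise FormatError(f"subject {sid!r}: unknown group {group!r}")
        if sid in seen:
            raise FormatError(f"duplicate subject_id {sid!r} in manifest")
        seen.add(sid)
        quip = float(sub["quip_rs"])
        if quip < 0:
            raise FormatError(f"subject {sid!r}: negative QUIP-RS score")
        sessions: dict[int, dict[str, str]] = {}
        for s, files in sub["sessions"].items():
            sessions[int(s)] = dict(files)
            if not lazy:
                for kind, fpath in files.items():
                    resolved = (path.parent / fpath)
                    if not resolved.exists():
                        raise FormatError(
                            f"subject {sid!r} session {s}: {kind} file not found: {fpath}"
                        )
        entries.append(ManifestEntry(sid, group, quip, sessions))
    return CohortManifest(seed=int(payload.get("seed", 0)), entries=entries)


# ---------------------------------------------------------------------------
# result tables


def write_peak_table(peaks: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table is missing columns {missing}")
    peaks.to_csv(path, index=False, columns=PEAK_COLUMNS, lineterminator="\n")
    return path


def read_peak_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"peak table is missing columns {missing}")
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_results_json(results: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(results), indent=2, sort_keys=True) + "\n")
    return path
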