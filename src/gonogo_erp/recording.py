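"""Continuous multichannel EEG for one subject-session."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import CHANNELS, DEFAULT_FS_HZ


@dataclass
class Recording:
    """Channels x samples EEG matrix in microvolts with montage metadata.

    Invariants: channel labels are unique, the sampling rate is positive,
    every sample is finite, and the data row count equals the label count.
    """

    subject_id: str
    session: int
    data: np.ndarray
    channel_labels: list[str] = field(default_factory=lambda: list(CHANNELS))
    fs_hz: float = DEFAULT_FS_HZ
    reference_note: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if len(self.channel_labels) != len(set(self.channel_labels)):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.session not in (1, 2):
            raise ValueError("session must be 1 or 2")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]
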