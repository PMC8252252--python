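"""Fixed 8-channel fronto-central montage used throughout the pipeline.

The recording setup places eight electrodes over the fronto-central
scalp — the region where Go/NoGo inhibition components (N2, P3) are
maximal — at standard 10-20 positions, sampled at 250 Hz.
"""

from __future__ import annotations

import numpy as np

#: Channel order is fixed; all arrays indexed by channel follow it.
CHANNELS: tuple[str, ...] = ("F3", "Fz", "F4", "FCz", "C3", "Cz", "C4", "CPz")

DEFAULT_FS_HZ: float = 250.0

#: Frontal / central channel subsets used by the ocular-component rule.
FRONTAL_CHANNELS: tuple[str, ...] = ("F3", "Fz", "F4")
CENTRAL_CHANNELS: tuple[str, ...] = ("C3", "Cz", "C4", "CPz")

#: Approximate 2-D scalp positions (x to the right, y to the front) on a
#: unit head circle, per the standard 10-20 layout.  Used for the
#: inverse-distance topographic maps.
POSITIONS_2D: dict[str, tuple[float, float]] = {
    "F3": (-0.35, 0.55),
    "Fz": (0.0, 0.55),
    "F4": (0.35, 0.55),
    "FCz": (0.0, 0.28),
    "C3": (-0.40, 0.0),
    "Cz": (0.0, 0.0),
    "C4": (0.40, 0.0),
    "CPz": (0.0, -0.28),
}


def channel_index(name: str) -> int:
    """Index of *name* in the fixed montage order."""
    try:
        return CHANNELS.index(name)
    except ValueError:
        raise KeyError(f"unknown channel {name!r}; montage is {CHANNELS}") from None


def channel_indices(names) -> np.ndarray:
    return np.array([channel_index(n) for n in names], dtype=int)
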