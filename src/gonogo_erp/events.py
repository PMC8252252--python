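"""Trial events of the Go/NoGo task and their behavioral annotation.

A session consists of blocks of visual stimuli: frequent Go targets
requiring a speeded button press and rare NoGo targets requiring the
response to be withheld.  Two behavioral error classes exist:

* SE (standard error): no press on a Go trial;
* CE (commission error): a press on a NoGo trial.

These definitions are invariants of :class:`TrialEvent` — an annotated
event can never carry an SE flag on a NoGo trial or a CE flag on a Go
trial, and a reaction time exists iff the button was pressed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional

GO = "Go"
NOGO = "NoGo"
CONDITIONS = (GO, NOGO)

ERROR_NONE = "none"
ERROR_SE = "SE"
ERROR_CE = "CE"
ERROR_TYPES = (ERROR_NONE, ERROR_SE, ERROR_CE)


@dataclass(frozen=True)
class TrialEvent:
    """One Go/NoGo stimulus with (optional) behavioral outcome.

    Parameters
    ----------
    onset_s
        Stimulus onset in seconds from recording start.
    condition
        ``"Go"`` or ``"NoGo"``.
    block_index
        Zero-based block number.
    pressed
        Whether the button was pressed; ``None`` for unannotated events.
    rt_ms
        Reaction time in milliseconds; present iff ``pressed`` is True.
    error_type
        ``"none"``, ``"SE"`` or ``"CE"`` per the task definitions.
    """

    onset_s: float
    condition: str
    block_index: int
    pressed: Optional[bool] = None
    rt_ms: Optional[float] = None
    error_type: str = ERROR_NONE

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.error_type not in ERROR_TYPES:
            raise ValueError(f"error_type must be one of {ERROR_TYPES}, got {self.error_type!r}")
        if self.block_index < 0:
            raise ValueError("block_index must be >= 0")
        if self.pressed is not None:
            self._check_annotation()

    def _check_annotation(self) -> None:
        if self.pressed:
            if self.rt_ms is None or self.rt_ms <= 0:
                raise ValueError("pressed trials must carry rt_ms > 0")
        elif self.rt_ms is not None:
            raise ValueError("rt_ms present on a trial without a press")
        expected = ERROR_NONE
        if self.condition == GO and not self.pressed:
            expected = ERROR_SE
        elif self.condition == NOGO and self.pressed:
            expected = ERROR_CE
        if self.error_type != expected:
            raise ValueError(
                f"error_type {self.error_type!r} inconsistent with "
                f"condition={self.condition}, pressed={self.pressed} "
                f"(expected {expected!r})"
            )

    @property
    def annotated(self) -> bool:
        return self.pressed is not None

    @property
    def is_error(self) -> bool:
        return self.error_type != ERROR_NONE

    def annotate(self, pressed: bool, rt_ms: Optional[float] = None) -> "TrialEvent":
        """Return a copy with the behavioral outcome filled in.

        The error flag is derived from (condition, pressed), never passed.
        """
        if self.condition == GO:
            error = ERROR_NONE if pressed else ERROR_SE
        else:
            error = ERROR_CE if pressed else ERROR_NONE
        return replace(
            self,
            pressed=pressed,
            rt_ms=float(rt_ms) if pressed else None,
            error_type=error,
        )


def validate_sequence(events: Iterable[TrialEvent]) -> list[TrialEvent]:
    """Check strictly increasing onsets; return the events as a list."""
    events = list(events)
    for prev, nxt in zip(events, events[1:]):
        if nxt.onset_s <= prev.onset_s:
            raise ValueError(
                f"onsets must be strictly increasing: {prev.onset_s} -> {nxt.onset_s}"
            )
    return events
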