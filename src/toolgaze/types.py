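"""Core record types shared across the pipeline.

The scene-camera coordinate system is the eye-tracker's 1280 x 960 pixel
frame sampled at a nominal 30 Hz.  Timestamps are integer milliseconds from
trial start (0-based) to avoid float drift at 30 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .errors import FormatError

#: Scene-camera frame size in pixels.
SCENE_WIDTH_PX = 1280.0
SCENE_HEIGHT_PX = 960.0

#: Nominal gaze sampling rate (Hz) and inter-sample interval (ms).
NOMINAL_RATE_HZ = 30.0
SAMPLE_INTERVAL_MS = 1000.0 / NOMINAL_RATE_HZ

# Movement-phase vocabulary.  "with_marble" covers transport of the marble
# from the cylinder base to the apex; "without_marble" covers the return of
# the empty chopsticks to the base; everything else (grasping, idle,
# between-cycle slack) is "other" and is not a transport phase.
WITH_MARBLE = "with_marble"
WITHOUT_MARBLE = "without_marble"
OTHER = "other"
PHASES = (WITH_MARBLE, WITHOUT_MARBLE, OTHER)
TRANSPORT_PHASES = (WITH_MARBLE, WITHOUT_MARBLE)

ANTICIPATORY = "anticipatory"
CONFIRMATORY = "confirmatory"
STRATEGIES = (ANTICIPATORY, CONFIRMATORY)


@dataclass
class GazeStream:
    """An ordered 30 Hz gaze-sample stream in scene-camera pixels.

    Parameters
    ----------
    t : int64 array, milliseconds from trial start, strictly increasing.
    x, y : float arrays, scene-camera pixel coordinates.
    valid : bool array; invalid samples are retained but flagged.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    trial_id: str = ""
    nominal_rate_hz: float = NOMINAL_RATE_HZ

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise FormatError("gaze stream columns have unequal lengths")
        if n > 1:
            bad = np.nonzero(np.diff(self.t) <= 0)[0]
            if bad.size:
                raise FormatError(
                    f"non-monotone timestamps: row {int(bad[0]) + 1} "
                    f"(t={int(self.t[bad[0] + 1])} after t={int(self.t[bad[0]])})"
                )

    def __len__(self) -> int:
        return len(self.t)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GazeStream):
            return NotImplemented
        return (
            self.trial_id == other.trial_id
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.valid, other.valid)
        )


class Point(NamedTuple):
    x: float
    y: float


@dataclass(frozen=True)
class FrameAnnotation:
    """Scene state for one video frame.

    ``tip`` is ``None`` when the chopstick tip is occluded (e.g. by the
    hand); fixations matched to such frames are excluded downstream with
    reason ``no_tip``.
    """

    t: int
    cyl_base: Point
    cyl_apex: Point
    tip: Optional[Point]
    phase: str
    in_setup: bool = True

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise FormatError(f"unknown phase label {self.phase!r}")
        if tuple(self.cyl_base) == tuple(self.cyl_apex):
            raise FormatError("cylinder base and apex coincide")


class Cycle(NamedTuple):
    """One grasp-transport-drop-return cycle (all times ms)."""

    grasp_onset: int
    grasp_success: int
    drop: int
    return_complete: int


@dataclass
class TrialEvents:
    """Event log for one 60 s trial."""

    trial_start: int
    trial_end: int
    cycles: list[Cycle] = field(default_factory=list)
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.trial_end <= self.trial_start:
            raise FormatError("trial_end must exceed trial_start")
        prev_end = self.trial_start
        for i, c in enumerate(self.cycles):
            ts = list(c)
            if any(b <= a for a, b in zip(ts, ts[1:])):
                raise FormatError(f"cycle {i}: timestamps not strictly increasing")
            if ts[0] < prev_end and i > 0:
                raise FormatError(f"cycle {i} overlaps the previous cycle")
            if ts[0] < self.trial_start or ts[-1] > self.trial_end:
                raise FormatError(f"cycle {i} outside trial bounds")
            prev_end = ts[-1]

    @property
    def duration_ms(self) -> int:
        return self.trial_end - self.trial_start

    @property
    def n_drops(self) -> int:
        return len(self.cycles)


def phase_at(events: TrialEvents, t: float) -> str:
    """Movement phase at time ``t`` implied by the trial's event log."""
    for c in events.cycles:
        if c.grasp_success <= t < c.drop:
            return WITH_MARBLE
        if c.drop <= t < c.return_complete:
            return WITHOUT_MARBLE
    return OTHER


def annotation_times(annotations: Sequence[FrameAnnotation]) -> np.ndarray:
    return np.asarray([a.t for a in annotations], dtype=np.int64)
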