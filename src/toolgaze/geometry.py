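"""Cylinder-referenced scene geometry.

The cylindrical container visible in every scene frame is the metric
reference: its known physical length fixes the pixel-to-millimetre scale,
and its image-plane axis defines the direction along which gaze leads or
trails the chopstick tip.  Because both scale and axis are re-measured per
frame, the resulting lead distance is invariant to the observer's head
pose — any similarity transform (rotation, translation, uniform scaling)
of the scene leaves it unchanged.

Sign convention: the goal direction points at the current movement goal —
toward the cylinder apex while transporting the marble, toward the base
while returning the empty chopsticks.  A positive lead means the fixation
is ahead of the tip on the way to the goal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import GeometryError
from .fixation import Fixation
from .types import WITH_MARBLE, WITHOUT_MARBLE, FrameAnnotation, annotation_times

#: Sentinel exclusion reason when the chopstick tip is not annotated.
NO_TIP = "no_tip"


@dataclass(frozen=True)
class CylinderFrame:
    """Per-frame cylinder reference: unit axis (base->apex), px length, scale."""

    axis: tuple[float, float]
    length_px: float
    mm_per_px: float
    t: int = 0


def cylinder_frame(ann: FrameAnnotation, physical_length_mm: float) -> CylinderFrame:
    """Build the metric reference frame from one annotation."""
    if physical_length_mm <= 0:
        raise GeometryError("physical cylinder length must be positive")
    v = np.asarray(ann.cyl_apex, dtype=float) - np.asarray(ann.cyl_base, dtype=float)
    length = float(np.hypot(*v))
    if length == 0.0:
        raise GeometryError("cylinder base and apex coincide")
    axis = v / length
    return CylinderFrame(
        axis=(float(axis[0]), float(axis[1])),
        length_px=length,
        mm_per_px=physical_length_mm / length,
        t=ann.t,
    )


def vertical_lead(
    fix_xy: Sequence[float],
    tip_xy: Sequence[float],
    cf: CylinderFrame,
    phase: str,
) -> float:
    """Signed along-axis lead of the fixation over the tip, in millimetres.

    Projects (fixation - tip) onto the goal direction: the cylinder axis
    during the with-marble phase, its negation during the without-marble
    return.  Positive = fixation leads the tip toward the goal.
    """
    if phase == WITH_MARBLE:
        g = np.asarray(cf.axis, dtype=float)
    elif phase == WITHOUT_MARBLE:
        g = -np.asarray(cf.axis, dtype=float)
    else:
        raise GeometryError(f"lead is undefined for phase {phase!r}")
    d = np.asarray(fix_xy, dtype=float) - np.asarray(tip_xy, dtype=float)
    return float(np.dot(d, g) * cf.mm_per_px)


def match_frame(annotations: Sequence[FrameAnnotation], t_ms: float) -> FrameAnnotation:
    """Annotation whose timestamp is nearest to ``t_ms`` (ties -> earlier)."""
    if not annotations:
        raise GeometryError("no annotations to match against")
    times = annotation_times(annotations)
    idx = int(np.searchsorted(times, t_ms))
    if idx == 0:
        return annotations[0]
    if idx >= len(times):
        return annotations[-1]
    # strictly closer later frame wins; ties go to the earlier frame
    if (times[idx] - t_ms) < (t_ms - times[idx - 1]):
        return annotations[idx]
    return annotations[idx - 1]


def fixation_lead(
    fix: Fixation,
    annotations: Sequence[FrameAnnotation],
    physical_length_mm: float,
) -> tuple[float | None, FrameAnnotation]:
    """Lead of a fixation against its midpoint-matched frame.

    Returns ``(lead_mm, frame)``; ``lead_mm`` is ``None`` when the matched
    frame has no tip annotation (exclusion reason ``no_tip``) or is not a
    transport frame.
    """
    ann = match_frame(annotations, fix.midpoint_ms)
    if ann.phase not in (WITH_MARBLE, WITHOUT_MARBLE) or ann.tip is None:
        return None, ann
    cf = cylinder_frame(ann, physical_length_mm)
    return vertical_lead(fix.centroid, ann.tip, cf, ann.phase), ann
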