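"""Transport-phase filtering and visual-strategy classification.

Each detected fixation is matched to the scene frame nearest its temporal
midpoint and then either excluded (with exactly one reason) or classified
along two axes:

* strategy — anticipatory if the fixation leads the chopstick tip toward
  the current movement goal by more than the lead threshold (36 mm by
  default), confirmatory otherwise (lead <= threshold, including negative
  leads trailing the tip);
* difficulty — with_marble (transporting the marble to the apex) or
  without_marble (returning the empty chopsticks to the base), taken from
  the annotated phase of the matched frame.

Exclusion reasons:

* ``not_transport`` — the matched frame's phase is not a transport phase;
* ``off_setup``    — the fixation centroid falls outside the experimental
  setup region of interest (or the frame is flagged out-of-setup);
* ``no_tip``       — the chopstick tip is occluded in the matched frame.

Counts are conserved: every detected fixation appears exactly once in the
output, classified or excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .config import RunConfig
from .errors import AlignmentError
from .fixation import Fixation
from .geometry import cylinder_frame, match_frame, vertical_lead
from .types import (
    ANTICIPATORY,
    CONFIRMATORY,
    OTHER,
    TRANSPORT_PHASES,
    FrameAnnotation,
    TrialEvents,
)

logger = logging.getLogger(__name__)

NOT_TRANSPORT = "not_transport"
OFF_SETUP = "off_setup"
NO_TIP = "no_tip"
EXCLUSION_REASONS = (NOT_TRANSPORT, OFF_SETUP, NO_TIP)


@dataclass(frozen=True)
class ClassifiedFixation:
    fixation: Fixation
    lead_mm: Optional[float] = None
    strategy: Optional[str] = None
    difficulty: Optional[str] = None
    exclusion_reason: Optional[str] = None
    trial_id: str = ""

    @property
    def kept(self) -> bool:
        return self.exclusion_reason is None


def filter_fixation(
    fix: Fixation,
    ann: FrameAnnotation,
    setup_roi: tuple[float, float, float, float],
) -> Optional[str]:
    """Return an exclusion reason for the fixation, or None to keep it.

    Checks are applied in the order of the analysis procedure: transport
    phase first, then the setup region, then tip visibility.
    """
    if ann.phase == OTHER:
        return NOT_TRANSPORT
    cx, cy = fix.centroid
    x0, y0, x1, y1 = setup_roi
    if not ann.in_setup or not (x0 <= cx <= x1 and y0 <= cy <= y1):
        return OFF_SETUP
    if ann.tip is None:
        return NO_TIP
    return None


def classify(lead_mm: float, threshold_mm: float = 36.0) -> str:
    """Anticipatory iff the lead strictly exceeds the threshold."""
    if not np.isfinite(lead_mm):
        raise ValueError("lead must be finite")
    return ANTICIPATORY if lead_mm > threshold_mm else CONFIRMATORY


def classify_trial(
    fixations: Sequence[Fixation],
    annotations: Sequence[FrameAnnotation],
    config: RunConfig,
    trial_id: str = "",
) -> list[ClassifiedFixation]:
    """Classify or exclude every fixation of one trial (counts conserved)."""
    out: list[ClassifiedFixation] = []
    for fix in fixations:
        ann = match_frame(annotations, fix.midpoint_ms)
        reason = filter_fixation(fix, ann, config.setup_roi)
        if reason is not None:
            out.append(
                ClassifiedFixation(fixation=fix, exclusion_reason=reason, trial_id=trial_id)
            )
            continue
        cf = cylinder_frame(ann, config.cylinder_physical_length_mm)
        lead = vertical_lead(fix.centroid, ann.tip, cf, ann.phase)
        out.append(
            ClassifiedFixation(
                fixation=fix,
                lead_mm=lead,
                strategy=classify(lead, config.lead_threshold_mm),
                difficulty=ann.phase,
                trial_id=trial_id,
            )
        )
    assert len(out) == len(fixations)
    return out


def classify_session(
    trials: Sequence[tuple[Sequence[Fixation], Sequence[FrameAnnotation], TrialEvents]],
    config: RunConfig,
) -> list[ClassifiedFixation]:
    """Classify all fixations of one session's analyzed trials.

    ``trials`` is a sequence of (fixations, annotations, events) triples,
    one per trial.  Raises :class:`AlignmentError` when a trial's fixations
    fall entirely outside the time range covered by its annotations.
    """
    out: list[ClassifiedFixation] = []
    for k, (fixations, annotations, events) in enumerate(trials):
        trial_id = getattr(events, "trial_id", "") or f"trial{k}"
        if fixations and annotations:
            t0, t1 = annotations[0].t, annotations[-1].t
            if all(f.end_ms < t0 or f.start_ms > t1 for f in fixations):
                raise AlignmentError(
                    f"{trial_id}: fixations [{fixations[0].start_ms}, "
                    f"{fixations[-1].end_ms}] ms do not overlap annotations "
                    f"[{t0}, {t1}] ms"
                )
        classified = classify_trial(fixations, annotations, config, trial_id)
        n_excl = sum(not c.kept for c in classified)
        logger.info(
            "%s: %d fixations, %d kept, %d excluded",
            trial_id, len(classified), len(classified) - n_excl, n_excl,
        )
        out.extend(classified)
    return out


def strategy_percentages(classified: Sequence[ClassifiedFixation]) -> dict:
    """Two-cell and four-cell strategy percentages of one session.

    Percentages are relative to the total number of classified (kept)
    fixations; each block sums to 100.  With zero kept fixations all
    entries are None ("missing"), never 0/0.
    """
    kept = [c for c in classified if c.kept]
    out: dict[str, Optional[float]] = {}
    cells = [(s, d) for s in (ANTICIPATORY, CONFIRMATORY) for d in TRANSPORT_PHASES]
    if not kept:
        logger.warning("no classified fixations; percentages undefined")
        out["anticipatory_pct"] = out["confirmatory_pct"] = None
        for s, d in cells:
            out[f"{s}_{d}_pct"] = None
        return out
    n = len(kept)
    n_ant = sum(c.strategy == ANTICIPATORY for c in kept)
    out["anticipatory_pct"] = 100.0 * n_ant / n
    out["confirmatory_pct"] = 100.0 * (n - n_ant) / n
    for s, d in cells:
        k = sum(c.strategy == s and c.difficulty == d for c in kept)
        out[f"{s}_{d}_pct"] = 100.0 * k / n
    return out


def fixations_per_drop(
    classified: Sequence[ClassifiedFixation],
    events: Sequence[TrialEvents],
) -> dict:
    """Per-strategy fixation counts normalized by successful marble drops.

    The denominator is the total drop count across the session's analyzed
    trials; with zero drops the rates are None (missing) with a warning.
    """
    drops = sum(ev.n_drops for ev in events)
    if drops == 0:
        logger.warning("zero successful drops; fixations-per-drop undefined")
        return {ANTICIPATORY: None, CONFIRMATORY: None}
    kept = [c for c in classified if c.kept]
    return {
        s: sum(c.strategy == s for c in kept) / drops
        for s in (ANTICIPATORY, CONFIRMATORY)
    }
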