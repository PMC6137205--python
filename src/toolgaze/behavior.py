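"""Behavioral performance metrics and the logarithmic learning curve.

Performance is quantified as marble drops per minute (MDPM): the number of
successful drop events in a 60 s trial (for a full-length trial the rate
equals the raw count).  Skill acquisition is summarized by an ordinary
least-squares fit of session-mean MDPM on the natural log of the 1-based
session index — the classic logarithmic practice curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ToolgazeError
from .types import ANTICIPATORY, CONFIRMATORY, TRANSPORT_PHASES, TrialEvents

logger = logging.getLogger(__name__)

NOMINAL_TRIAL_MS = 60_000


def mdpm(events: TrialEvents) -> float:
    """Successful marble drops per minute for one trial.

    Truncated trials (duration != 60 s) are rate-normalized to drops/min
    and flagged with a warning rather than rejected.
    """
    dur = events.duration_ms
    if dur <= 0:
        raise ToolgazeError("trial duration must be positive")
    if dur != NOMINAL_TRIAL_MS:
        warnings.warn(
            f"trial {events.trial_id or '?'} lasted {dur} ms, not 60 s; "
            "MDPM rate-normalized",
            stacklevel=2,
        )
    return events.n_drops * 60_000.0 / dur


def phase_durations(events: TrialEvents) -> tuple[float, float, float]:
    """Mean (grasp, lift-drop, return) durations in ms across cycles.

    grasp    = grasp_success - grasp_onset
    liftdrop = drop - grasp_success
    return   = return_complete - drop
    """
    if not events.cycles:
        raise InsufficientDataError("no complete cycles to average")
    arr = np.asarray(events.cycles, dtype=float)
    grasp = arr[:, 1] - arr[:, 0]
    liftdrop = arr[:, 2] - arr[:, 1]
    ret = arr[:, 3] - arr[:, 2]
    return float(grasp.mean()), float(liftdrop.mean()), float(ret.mean())


@dataclass(frozen=True)
class LearningCurveFit:
    a: float          # intercept: expected performance at session 1
    b: float          # slope per ln(session)
    r_squared: float

    def predict(self, session: np.ndarray | float) -> np.ndarray | float:
        return self.a + self.b * np.log(session)


def fit_log_curve(
    session_means: Sequence[float],
    sessions: Sequence[int] | None = None,
) -> LearningCurveFit:
    """OLS fit of session-mean performance on ln(session index), 1-based."""
    y = np.asarray(session_means, dtype=float)
    if sessions is None:
        sessions = np.arange(1, len(y) + 1)
    s = np.asarray(sessions, dtype=float)
    if len(y) < 3:
        raise InsufficientDataError("log-curve fit needs at least 3 sessions")
    if np.any(s < 1):
        raise ToolgazeError("session indices are 1-based")
    X = np.column_stack([np.ones_like(s), np.log(s)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0.0 else 1.0 - float((resid**2).sum()) / tss
    return LearningCurveFit(a=float(coef[0]), b=float(coef[1]), r_squared=r2)


@dataclass
class SessionSummary:
    """Per subject x session aggregates feeding the statistics layer.

    Gaze-derived fields are None for sessions without eye-tracking
    recordings (only the first and final sessions are recorded in the
    study design this pipeline mirrors).
    """

    subject_id: str
    session_idx: int
    mdpm_per_trial: list[float] = field(default_factory=list)
    mdpm_mean: float = float("nan")
    mdpm_sem: float = float("nan")
    grasp_ms_mean: float = float("nan")
    liftdrop_ms_mean: float = float("nan")
    return_ms_mean: float = float("nan")
    # gaze-derived (recorded sessions only)
    percentages: Optional[dict] = None
    fixations_per_drop: Optional[dict] = None
    mean_duration_ms: Optional[dict] = None  # keyed (strategy, difficulty)
    mean_lead_mm: Optional[dict] = None      # keyed (strategy, difficulty)


def summarize_behavior(
    subject_id: str, session_idx: int, trials: Sequence[TrialEvents]
) -> SessionSummary:
    """Behavioral aggregates for one subject x session (5 trials default)."""
    if not trials:
        raise InsufficientDataError("no trials to summarize")
    per_trial = [mdpm(ev) for ev in trials]
    phases = [phase_durations(ev) for ev in trials if ev.cycles]
    arr = np.asarray(per_trial, dtype=float)
    sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else float("nan")
    if phases:
        ph = np.asarray(phases, dtype=float).mean(axis=0)
    else:
        ph = np.full(3, np.nan)
    return SessionSummary(
        subject_id=subject_id,
        session_idx=session_idx,
        mdpm_per_trial=per_trial,
        mdpm_mean=float(arr.mean()),
        mdpm_sem=sem,
        grasp_ms_mean=float(ph[0]),
        liftdrop_ms_mean=float(ph[1]),
        return_ms_mean=float(ph[2]),
    )


def gaze_cell_means(classified) -> tuple[dict, dict]:
    """Mean fixation duration and lead per strategy x difficulty cell."""
    dur: dict = {}
    lead: dict = {}
    kept = [c for c in classified if c.kept]
    for s in (ANTICIPATORY, CONFIRMATORY):
        for d in TRANSPORT_PHASES:
            cell = [c for c in kept if c.strategy == s and c.difficulty == d]
            if cell:
                dur[(s, d)] = float(np.mean([c.fixation.duration_ms for c in cell]))
                lead[(s, d)] = float(np.mean([c.lead_mm for c in cell]))
            else:
                dur[(s, d)] = None
                lead[(s, d)] = None
    return dur, lead


# column order of the flat summary table (one row per subject x session)
_SUMMARY_SCALARS = [
    "mdpm_mean", "mdpm_sem",
    "grasp_ms_mean", "liftdrop_ms_mean", "return_ms_mean",
]


def summaries_to_frame(summaries: Sequence[SessionSummary]) -> pd.DataFrame:
    """Flatten SessionSummary records into one tidy DataFrame."""
    rows = []
    for s in summaries:
        row: dict = {"subject_id": s.subject_id, "session_idx": s.session_idx}
        for name in _SUMMARY_SCALARS:
            row[name] = getattr(s, name)
        row["mdpm_per_trial"] = ";".join(f"{v:.6g}" for v in s.mdpm_per_trial)
        if s.percentages:
            row.update(s.percentages)
        if s.fixations_per_drop:
            for k, v in s.fixations_per_drop.items():
                row[f"{k}_per_drop"] = v
        for prefix, table in (("dur", s.mean_duration_ms), ("lead", s.mean_lead_mm)):
            if table:
                for (strat, diff), v in table.items():
                    row[f"{prefix}_{strat}_{diff}"] = v
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["subject_id", "session_idx"]).reset_index(drop=True)
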