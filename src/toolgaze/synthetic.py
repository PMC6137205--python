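"""Synthetic multi-subject gaze / scene / event datasets with known truth.

The generator emulates a tool-use motor-learning study: subjects practice
grasping marbles with chopsticks and dropping them into a cylinder over
eight sessions (five analyzed 60 s trials per session), with head-mounted
eye tracking (30 Hz scene camera, 1280 x 960 px) recorded in the first and
final sessions.

Generating model
----------------
* Behavioral performance follows a logarithmic practice curve: the trial
  drop count is ``round(max(0, a + b*ln(session) + u_subject + e_trial))``
  with Gaussian subject and trial effects.  Defaults ``a=14.390``,
  ``b=8.946`` are the OLS fit of the published session-mean performance
  anchors on ln(session).
* Each drop cycle has grasp / lift-drop / return phases whose mean
  durations interpolate log-linearly between first-session and
  final-session anchors.  Phase durations scale with the trial's realized
  speed (fast trials have proportionally faster phases); an analytic
  normalization keeps per-trial mean phase durations unbiased for the
  anchors.
* Each cycle's two transport segments (with marble: base->apex; without
  marble: apex->base) contain 1-3 fixations each.  Every fixation draws a
  strategy (anticipatory with a session-interpolated probability), a
  duration, and a signed lead distance along the cylinder axis;
  anticipatory leads are drawn safely above the 36 mm classification
  threshold, confirmatory leads below it.
* Gaze samples within a fixation are the intended point plus small
  isotropic jitter; fixations are separated by 2-4 scatter samples whose
  consecutive displacements exceed the detector's dispersion threshold,
  which guarantees separability.
* Every trial is viewed through a random similarity transform (head pose:
  rotation, uniform scale, translation) applied to gaze, tip and cylinder
  alike; cylinder-referenced leads are invariant to it by construction.

All randomness flows through one seeded generator; identical parameters
and seed reproduce byte-identical datasets.
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

from .errors import ConfigurationError
from .types import (
    ANTICIPATORY,
    CONFIRMATORY,
    OTHER,
    WITH_MARBLE,
    WITHOUT_MARBLE,
    Cycle,
    FrameAnnotation,
    GazeStream,
    Point,
    TrialEvents,
)

logger = logging.getLogger(__name__)

#: exact inter-sample interval at 30 Hz (ms)
DT_MS = 1000.0 / 30.0

# canonical (pre-transform) scene: vertical cylinder centred in the frame
CANON_BASE = np.array([640.0, 700.0])
CANON_APEX = np.array([640.0, 400.0])
CANON_CENTER = np.array([640.0, 480.0])
CANON_LENGTH_PX = 300.0

# confirmatory leads sit at/near the tool-object interaction, strictly
# below the 36 mm threshold with a 2 mm guard band; anticipatory leads sit
# strictly above it.  (mm)
CONF_LEAD_MEAN, CONF_LEAD_SD = 12.0, 10.0
CONF_LEAD_LO, CONF_LEAD_HI = -20.0, 34.0
ANT_LEAD_LO, ANT_LEAD_HI = 38.0, 200.0

_SCATTER_MIN_L1 = 160.0  # px; forces >100 px dispersion across any break
_SCATTER_R_LO, _SCATTER_R_HI = 250.0, 410.0


@dataclass(frozen=True)
class LearningParams:
    """Generating parameters for the synthetic study.

    Defaults reproduce the study conditions: 12 subjects, 8 sessions,
    5 analyzed trials per session, performance anchors on the logarithmic
    curve, a 42.4% -> 55.8% anticipatory-share shift between the first and
    final recorded sessions, and first/final phase-duration anchors.
    """

    a: float = 14.390          # MDPM intercept (drops/min at session 1)
    b: float = 8.946           # drops/min per ln(session); >= 0
    sigma_subject: float = 5.0  # between-subject SD of the intercept
    sigma_trial: float = 3.0   # trial-level noise SD (free choice, see docs)
    p_anticipatory_first: float = 0.42367
    p_anticipatory_final: float = 0.55761
    mu_dur_conf_first: float = 208.573   # ms
    mu_dur_conf_final: float = 166.534   # ms
    mu_dur_ant: float = 206.565          # ms, training-invariant
    sigma_dur: float = 40.0
    dur_without_offset_ms: float = 25.0  # without-marble fixations run longer
    mu_lead_with: float = 55.0           # anticipatory mean lead (mm)
    mu_lead_without: float = 65.0
    sigma_lead: float = 8.0
    phase_means_first: tuple[float, float, float] = (1750.0, 748.0, 1006.0)
    phase_means_final: tuple[float, float, float] = (690.0, 449.0, 606.0)
    phase_cv: float = 0.08
    n_subjects: int = 12
    n_sessions: int = 8
    n_trials_per_session: int = 5
    trial_duration_s: float = 60.0
    recorded_sessions: Optional[tuple[int, ...]] = None  # None -> (1, last)
    fix_per_segment: tuple[int, int] = (1, 3)
    p_grasp_fixation: float = 0.10   # extra non-transport fixation per cycle
    p_tip_missing: float = 0.02      # per transport frame
    invalid_rate: float = 0.0
    jitter_px: float = 3.0
    cylinder_length_mm: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_anticipatory_first", "p_anticipatory_final",
                     "p_grasp_fixation", "p_tip_missing", "invalid_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.b < 0:
            raise ConfigurationError("b must be >= 0 (non-decreasing performance)")
        for name in ("mu_dur_conf_first", "mu_dur_conf_final", "mu_dur_ant",
                     "cylinder_length_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.trial_duration_s <= 0:
            raise ConfigurationError("trial_duration_s must be positive")
        if self.n_subjects < 1 or self.n_sessions < 1 or self.n_trials_per_session < 1:
            raise ConfigurationError("need at least one subject, session and trial")
        if self.sigma_subject < 0 or self.sigma_trial < 0 or self.sigma_dur < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        lo, hi = self.fix_per_segment
        if not (1 <= lo <= hi):
            raise ConfigurationError("fix_per_segment bounds must satisfy 1 <= lo <= hi")

    # -- session-indexed generating quantities ---------------------------

    @property
    def sessions_recorded(self) -> tuple[int, ...]:
        if self.recorded_sessions is not None:
            return self.recorded_sessions
        if self.n_sessions == 1:
            return (1,)
        return (1, self.n_sessions)

    @property
    def trial_ms(self) -> int:
        return int(round(self.trial_duration_s * 1000))

    def mean_rate(self, session: int) -> float:
        """Expected drop rate a + b*ln(s) before noise/truncation."""
        return self.a + self.b * math.log(session)

    def _frac(self, session: int) -> float:
        if self.n_sessions == 1:
            return 0.0
        return (session - 1) / (self.n_sessions - 1)

    def p_anticipatory(self, session: int) -> float:
        """Linear interpolation of the anticipatory share across sessions."""
        f = self._frac(session)
        return self.p_anticipatory_first + f * (
            self.p_anticipatory_final - self.p_anticipatory_first
        )

    def mu_dur_conf(self, session: int) -> float:
        f = self._frac(session)
        return self.mu_dur_conf_first + f * (self.mu_dur_conf_final - self.mu_dur_conf_first)

    def mu_duration(self, strategy: str, difficulty: str, session: int) -> float:
        mu = self.mu_dur_ant if strategy == ANTICIPATORY else self.mu_dur_conf(session)
        if difficulty == WITHOUT_MARBLE:
            mu += self.dur_without_offset_ms
        return mu

    def phase_means(self, session: int) -> tuple[float, float, float]:
        """Log-linear interpolation of grasp/lift-drop/return means (ms)."""
        if self.n_sessions == 1:
            return self.phase_means_first
        w = math.log(session) / math.log(self.n_sessions)
        return tuple(
            f0 + w * (f1 - f0)
            for f0, f1 in zip(self.phase_means_first, self.phase_means_final)
        )

    def lead_bounds(self, strategy: str, difficulty: str) -> tuple[float, float, float, float]:
        """(mu, sd, lo, hi) of the truncated-normal lead for one cell (mm)."""
        if strategy == ANTICIPATORY:
            mu = self.mu_lead_with if difficulty == WITH_MARBLE else self.mu_lead_without
            return mu, self.sigma_lead, ANT_LEAD_LO, ANT_LEAD_HI
        return CONF_LEAD_MEAN, CONF_LEAD_SD, CONF_LEAD_LO, CONF_LEAD_HI

    def lead_dist(self, strategy: str, difficulty: str):
        """Frozen truncated-normal lead distribution for one cell (mm)."""
        mu, sd, lo, hi = self.lead_bounds(strategy, difficulty)
        return stats.truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd)


def _trunc_norm_rvs(rng: np.random.Generator, mu: float, sd: float,
                    lo: float, hi: float) -> float:
    """One draw from N(mu, sd) truncated to [lo, hi] via inverse CDF."""
    if sd <= 0:
        return min(max(mu, lo), hi)
    fa = ndtr((lo - mu) / sd)
    fb = ndtr((hi - mu) / sd)
    return mu + sd * float(ndtri(rng.uniform(fa, fb)))


# ---------------------------------------------------------------------------
# ground truth


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form expectations of what the pipeline estimates."""

    mdpm: dict                 # session -> E[MDPM]
    p_anticipatory: dict       # session -> anticipatory share (recorded)
    phase_means_ms: dict       # session -> (grasp, liftdrop, return)
    duration_ms: dict          # (strategy, difficulty, session) -> E[duration]
    lead_mm: dict              # (strategy, difficulty) -> E[lead]


def _expected_rounded_truncated(mu: float, sigma: float) -> float:
    """E[round(max(X, 0))] for X ~ N(mu, sigma)."""
    if sigma == 0.0:
        return float(round(max(mu, 0.0)))
    hi = int(math.ceil(mu + 10 * sigma))
    ks = np.arange(1, hi + 1)
    upper = stats.norm.cdf((ks + 0.5 - mu) / sigma)
    lower = stats.norm.cdf((ks - 0.5 - mu) / sigma)
    return float(np.sum(ks * (upper - lower)))


def _expected_quantized_duration(mu: float, sigma: float) -> float:
    """E[DT * max(3, round(D / DT))] for D ~ N(mu, sigma) (ms).

    The generator realizes a fixation as n = max(4, round(D/DT)+1) samples,
    so its measured first-to-last span is DT * max(3, round(D/DT)).
    """
    if sigma == 0.0:
        return DT_MS * max(3, round(mu / DT_MS))
    hi = int(math.ceil((mu + 10 * sigma) / DT_MS))
    js = np.arange(0, hi + 1)
    upper = stats.norm.cdf(((js + 0.5) * DT_MS - mu) / sigma)
    lower = stats.norm.cdf(((js - 0.5) * DT_MS - mu) / sigma)
    probs = upper - lower
    probs[-1] += 1.0 - upper[-1]
    return float(DT_MS * np.sum(np.maximum(js, 3) * probs))


@functools.lru_cache(maxsize=512)
def _speed_norm(abar: float, sigma: float) -> float:
    """E[abar / max(m, 1) | at least one drop], m ~ N(abar, sigma).

    Normalization constant that keeps speed-scaled phase durations
    unbiased per trial.
    """
    if sigma == 0.0:
        return abar / max(abar, 1.0) if round(max(abar, 0.0)) >= 1 else 1.0
    z = np.linspace(-8.0, 8.0, 16001)
    w = stats.norm.pdf(z)
    m = abar + sigma * z
    alive = np.round(np.maximum(m, 0.0)) >= 1
    if not np.any(alive):
        return 1.0
    num = np.sum(w[alive] * (abar / np.maximum(m[alive], 1.0)))
    den = np.sum(w[alive])
    return float(num / den)


def ground_truth(params: LearningParams) -> GroundTruth:
    sigma_tot = math.hypot(params.sigma_subject, params.sigma_trial)
    mdpm = {
        s: _expected_rounded_truncated(params.mean_rate(s), sigma_tot)
        * (60_000.0 / params.trial_ms)
        for s in range(1, params.n_sessions + 1)
    }
    p_ant = {s: params.p_anticipatory(s) for s in params.sessions_recorded}
    phases = {s: params.phase_means(s) for s in range(1, params.n_sessions + 1)}
    durations = {}
    for s in params.sessions_recorded:
        for strat in (ANTICIPATORY, CONFIRMATORY):
            for diff in (WITH_MARBLE, WITHOUT_MARBLE):
                durations[(strat, diff, s)] = _expected_quantized_duration(
                    params.mu_duration(strat, diff, s), params.sigma_dur
                )
    leads = {}
    for strat in (ANTICIPATORY, CONFIRMATORY):
        for diff in (WITH_MARBLE, WITHOUT_MARBLE):
            mu, sd, lo, hi = params.lead_bounds(strat, diff)
            leads[(strat, diff)] = (
                min(max(mu, lo), hi) if sd == 0
                else float(params.lead_dist(strat, diff).mean())
            )
    return GroundTruth(
        mdpm=mdpm, p_anticipatory=p_ant, phase_means_ms=phases,
        duration_ms=durations, lead_mm=leads,
    )


# ---------------------------------------------------------------------------
# trial construction


@dataclass
class TrialData:
    session: int
    trial_idx: int
    trial_id: str
    events: TrialEvents
    truth: pd.DataFrame
    gaze: Optional[GazeStream] = None
    annotations: Optional[list[FrameAnnotation]] = None


@dataclass
class SubjectDataset:
    subject_id: str
    sessions: dict = field(default_factory=dict)  # session -> list[TrialData]

    def trials(self, session: int) -> list:
        return self.sessions[session]


def _sample_time(i: int) -> int:
    return (i * 1000) // 30


def _first_sample_at_or_after(t_ms: float) -> int:
    i = int(math.ceil(t_ms * 30.0 / 1000.0))
    while _sample_time(i) < t_ms:
        i += 1
    while i > 0 and _sample_time(i - 1) >= t_ms:
        i -= 1
    return i


def _plan_events(params: LearningParams, session: int, m: float,
                 rng: np.random.Generator, speed_norm: float) -> tuple[TrialEvents, float]:
    """Draw the cycle structure of one trial; returns (events, speed)."""
    trial_ms = params.trial_ms
    k = int(round(max(m, 0.0)))
    if k == 0:
        return TrialEvents(trial_start=0, trial_end=trial_ms), 1.0
    abar = params.mean_rate(session)
    speed = (abar / max(m, 1.0)) / speed_norm
    means = params.phase_means(session)
    factors = np.maximum(0.2, 1.0 + params.phase_cv * rng.standard_normal((k, 3)))
    durs = np.maximum(30.0, np.asarray(means) * speed * factors)  # (k, 3) ms
    total = float(durs.sum())
    budget = trial_ms - (k + 1)
    if total > budget:
        logger.debug("compressing cycles: total %.0f ms > budget %d ms", total, budget)
        durs *= budget / total
        total = budget
    # keep a couple of ms of headroom so integer rounding (which may force
    # +1 ms per cycle boundary) can never push past the trial end
    slack = max(trial_ms - total - (k + 2), 0.0)
    gaps = rng.dirichlet(np.ones(k + 1)) * slack
    cycles = []
    cursor = 0.0
    prev = 0
    for i in range(k):
        cursor += gaps[i]
        ts_f = [cursor, cursor + durs[i, 0], cursor + durs[i, 0] + durs[i, 1],
                cursor + durs[i].sum()]
        ts = []
        for v in ts_f:
            iv = max(prev + 1, int(round(v)))
            ts.append(iv)
            prev = iv
        cycles.append(Cycle(*ts))
        cursor = ts[-1]
    # guard against rounding pushing past the trial end
    if cycles and cycles[-1].return_complete > trial_ms:
        raise AssertionError("cycle layout exceeded trial duration")
    return TrialEvents(trial_start=0, trial_end=trial_ms, cycles=cycles), speed


_TRUTH_COLUMNS = [
    "i0", "i1", "start_ms", "end_ms", "n_samples", "strategy", "difficulty",
    "lead_mm", "duration_ms", "excluded_reason",
]


def _plan_fixations(params: LearningParams, session: int, events: TrialEvents,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Schedule fixation epochs on the 30 Hz sample grid; returns truth table.

    A fixation belongs to the segment that contains its temporal midpoint
    (the frame the classifier will match); its tail may spill past the
    segment boundary, as real fixations straddle phase transitions.  The
    room check before each draw uses the worst-case fixation length of the
    segment's cell — never the strategy actually drawn — so short segments
    thin the fixation count without biasing the strategy mix or the
    per-cell duration and lead distributions.
    """
    rows = []
    lo, hi = params.fix_per_segment
    n_total = _first_sample_at_or_after(events.trial_end - events.trial_start)
    cursor = 1  # global sample cursor; fixations never overlap
    for cyc in events.cycles:
        segments = [
            (WITH_MARBLE, cyc.grasp_success, cyc.drop),
            (WITHOUT_MARBLE, cyc.drop, cyc.return_complete),
        ]
        # occasional non-transport fixation during the grasp phase
        if rng.random() < params.p_grasp_fixation:
            segments.insert(0, (OTHER, cyc.grasp_onset, cyc.grasp_success))
        for difficulty, seg_start, seg_end in segments:
            i0 = _first_sample_at_or_after(seg_start)
            i1 = _first_sample_at_or_after(seg_end)
            cursor = max(cursor, i0 + 1)
            n_fix = 1 if difficulty == OTHER else int(rng.integers(lo, hi + 1))
            mu_cap = max(
                params.mu_duration(s, difficulty if difficulty != OTHER else WITH_MARBLE,
                                   session)
                for s in (ANTICIPATORY, CONFIRMATORY)
            )
            n_cap = max(4, int(round((mu_cap + 4.0 * params.sigma_dur) / DT_MS)) + 1)
            half_cap = n_cap // 2  # midpoint-frame offset upper bound
            for _ in range(n_fix):
                if cursor + half_cap > i1 - 1 or cursor + n_cap + 1 > n_total - 1:
                    break  # worst-case midpoint would leave the segment
                if difficulty == OTHER:
                    strategy = None
                    mu = params.mu_dur_conf(session)
                    lead = 0.0
                else:
                    strategy = (
                        ANTICIPATORY
                        if rng.random() < params.p_anticipatory(session)
                        else CONFIRMATORY
                    )
                    mu = params.mu_duration(strategy, difficulty, session)
                    lead = _trunc_norm_rvs(rng, *params.lead_bounds(strategy, difficulty))
                d = rng.normal(mu, params.sigma_dur)
                n = min(max(4, int(round(d / DT_MS)) + 1), n_cap)
                rows.append({
                    "i0": cursor,
                    "i1": cursor + n - 1,
                    "start_ms": _sample_time(cursor),
                    "end_ms": _sample_time(cursor + n - 1),
                    "n_samples": n,
                    "strategy": strategy,
                    "difficulty": difficulty if difficulty != OTHER else None,
                    "lead_mm": lead,
                    "duration_ms": _sample_time(cursor + n - 1) - _sample_time(cursor),
                    "excluded_reason": "not_transport" if difficulty == OTHER else None,
                })
                cursor += n + int(rng.integers(2, 5))
    return pd.DataFrame(rows, columns=_TRUTH_COLUMNS)


def _tip_canonical(events: TrialEvents, times: np.ndarray) -> np.ndarray:
    """Chopstick-tip canonical trajectory sampled at the gaze timestamps."""
    pos = np.tile(CANON_BASE, (len(times), 1))
    for c in events.cycles:
        up = (times >= c.grasp_success) & (times < c.drop)
        if np.any(up):
            w = (times[up] - c.grasp_success) / (c.drop - c.grasp_success)
            pos[up] = CANON_BASE + np.outer(w, CANON_APEX - CANON_BASE)
        down = (times >= c.drop) & (times < c.return_complete)
        if np.any(down):
            w = (times[down] - c.drop) / (c.return_complete - c.drop)
            pos[down] = CANON_APEX + np.outer(w, CANON_BASE - CANON_APEX)
    return pos


def _nearest_frame(times: np.ndarray, t: float) -> int:
    idx = int(np.searchsorted(times, t))
    if idx == 0:
        return 0
    if idx >= len(times):
        return len(times) - 1
    return idx if (times[idx] - t) < (t - times[idx - 1]) else idx - 1


def _scatter_point(rng: np.random.Generator, prev: np.ndarray,
                   avoid: Optional[np.ndarray]) -> np.ndarray:
    """Random canonical point far (L1) from the previous sample and the
    next fixation location, inside the transform-safe disc."""
    for _ in range(40):
        r = rng.uniform(_SCATTER_R_LO, _SCATTER_R_HI)
        th = rng.uniform(0.0, 2.0 * math.pi)
        p = CANON_CENTER + r * np.array([math.cos(th), math.sin(th)])
        if np.abs(p - prev).sum() < _SCATTER_MIN_L1:
            continue
        if avoid is not None and np.abs(p - avoid).sum() < _SCATTER_MIN_L1:
            continue
        return p
    return CANON_CENTER + np.array([0.0, -_SCATTER_R_HI])  # deterministic fallback


def _materialize(params: LearningParams, events: TrialEvents, truth: pd.DataFrame,
                 rng: np.random.Generator, trial_id: str,
                 ) -> tuple[GazeStream, list[FrameAnnotation]]:
    """Render the planned trial into gaze samples and frame annotations."""
    n_samples = _first_sample_at_or_after(events.trial_end - events.trial_start)
    times = np.array([_sample_time(i) for i in range(n_samples)], dtype=np.int64)
    tip = _tip_canonical(events, times.astype(float))
    scale = params.cylinder_length_mm / CANON_LENGTH_PX  # mm per canonical px
    axis = (CANON_APEX - CANON_BASE) / CANON_LENGTH_PX

    pos = np.full((n_samples, 2), np.nan)
    owner = np.full(n_samples, -1)
    fix_anchor = np.full((n_samples, 2), np.nan)  # intended point per sample
    for ridx, row in truth.iterrows():
        i0, i1 = int(row.i0), int(row.i1)
        mid = 0.5 * (row.start_ms + row.end_ms)
        m_idx = _nearest_frame(times, mid)
        goal = axis if row.difficulty != WITHOUT_MARBLE else -axis
        anchor = tip[m_idx] + goal * (row.lead_mm / scale)
        jit = np.clip(
            rng.normal(0.0, params.jitter_px, size=(i1 - i0 + 1, 2)),
            -3.5 * params.jitter_px, 3.5 * params.jitter_px,
        )
        pos[i0 : i1 + 1] = anchor + jit
        owner[i0 : i1 + 1] = ridx
        fix_anchor[i0 : i1 + 1] = anchor

    prev = CANON_CENTER + np.array([_SCATTER_R_HI, 0.0])
    for i in range(n_samples):
        if owner[i] >= 0:
            prev = fix_anchor[i]
            continue
        nxt = fix_anchor[i + 1] if i + 1 < n_samples and owner[i + 1] >= 0 else None
        p = _scatter_point(rng, prev, nxt)
        pos[i] = p
        prev = p

    # head pose: one similarity transform per trial
    theta = rng.uniform(-math.pi / 12, math.pi / 12)
    s_fac = rng.uniform(0.9, 1.1)
    trans = rng.uniform(-20.0, 20.0, size=2)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])

    def xf(p: np.ndarray) -> np.ndarray:
        return (p - CANON_CENTER) @ (s_fac * rot).T + CANON_CENTER + trans

    gaze_xy = xf(pos)
    tip_xy = xf(tip)
    base_pt = Point(*np.round(xf(CANON_BASE[None, :])[0], 3))
    apex_pt = Point(*np.round(xf(CANON_APEX[None, :])[0], 3))

    valid = np.ones(n_samples, dtype=bool)
    if params.invalid_rate > 0:
        valid &= rng.random(n_samples) >= params.invalid_rate
    gaze = GazeStream(
        t=times,
        x=np.round(np.clip(gaze_xy[:, 0], 0.0, 1280.0), 3),
        y=np.round(np.clip(gaze_xy[:, 1], 0.0, 960.0), 3),
        valid=valid,
        trial_id=trial_id,
    )

    annotations = []
    phase_arr = np.full(n_samples, OTHER, dtype=object)
    for c in events.cycles:
        phase_arr[(times >= c.grasp_success) & (times < c.drop)] = WITH_MARBLE
        phase_arr[(times >= c.drop) & (times < c.return_complete)] = WITHOUT_MARBLE
    tip_missing = rng.random(n_samples) < params.p_tip_missing
    for i in range(n_samples):
        in_transport = phase_arr[i] != OTHER
        show_tip = not (in_transport and tip_missing[i])
        annotations.append(
            FrameAnnotation(
                t=int(times[i]),
                cyl_base=base_pt,
                cyl_apex=apex_pt,
                tip=Point(*np.round(tip_xy[i], 3)) if show_tip else None,
                phase=str(phase_arr[i]),
                in_setup=True,
            )
        )
    return gaze, annotations


def simulate_subject(
    params: LearningParams,
    subject_id: str,
    rng_seed,
    materialize: bool = True,
) -> SubjectDataset:
    """Simulate every session and trial of one subject.

    ``rng_seed`` may be an int or a ``numpy.random.SeedSequence``.  With
    ``materialize=False`` only event logs and the ground-truth fixation
    schedule are produced (gaze/annotations omitted); the plan is
    identical either way.
    """
    ss = (
        rng_seed
        if isinstance(rng_seed, np.random.SeedSequence)
        else np.random.SeedSequence(rng_seed)
    )
    n_trials_total = params.n_sessions * params.n_trials_per_session
    children = ss.spawn(1 + n_trials_total)
    rng_subject = np.random.default_rng(children[0])
    u_subject = rng_subject.normal(0.0, params.sigma_subject)

    recorded = set(params.sessions_recorded)
    speed_norms = {
        s: _speed_norm(params.mean_rate(s),
                       math.hypot(params.sigma_subject, params.sigma_trial))
        for s in range(1, params.n_sessions + 1)
    }
    dataset = SubjectDataset(subject_id=subject_id)
    child_i = 1
    for s in range(1, params.n_sessions + 1):
        trials = []
        for ti in range(params.n_trials_per_session):
            plan_ss, mat_ss = children[child_i].spawn(2)
            child_i += 1
            plan_rng = np.random.default_rng(plan_ss)
            m = params.mean_rate(s) + u_subject + plan_rng.normal(0.0, params.sigma_trial)
            events, _speed = _plan_events(params, s, m, plan_rng, speed_norms[s])
            trial_id = f"{subject_id}_s{s}_t{ti + 1}"
            events.trial_id = trial_id
            if s in recorded:
                truth = _plan_fixations(params, s, events, plan_rng)
            else:
                truth = pd.DataFrame(columns=_TRUTH_COLUMNS)
            trial = TrialData(
                session=s, trial_idx=ti + 1, trial_id=trial_id,
                events=events, truth=truth,
            )
            if materialize and s in recorded:
                mat_rng = np.random.default_rng(mat_ss)
                trial.gaze, trial.annotations = _materialize(
                    params, events, truth, mat_rng, trial_id
                )
            trials.append(trial)
        dataset.sessions[s] = trials
    return dataset


def simulate_dataset(
    params: LearningParams, materialize: bool = True
) -> list[SubjectDataset]:
    """Simulate the full multi-subject study from ``params.seed``."""
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(params.n_subjects)
    return [
        simulate_subject(params, f"S{i + 1:02d}", child, materialize=materialize)
        for i, child in enumerate(children)
    ]


def truth_summaries(datasets: Sequence[SubjectDataset],
                    params: LearningParams) -> pd.DataFrame:
    """Per subject x session summary table from generator truth labels.

    Uses the generator's intended fixation labels instead of running the
    detection/classification stages; suited to large Monte-Carlo recovery
    and null-calibration runs where the detector's fidelity is
    established separately.
    """
    from .behavior import summaries_to_frame, summarize_behavior

    recorded = set(params.sessions_recorded)
    out = []
    for ds in datasets:
        for s, trials in sorted(ds.sessions.items()):
            summary = summarize_behavior(ds.subject_id, s, [t.events for t in trials])
            if s in recorded:
                frames = [t.truth for t in trials if len(t.truth)]
                truth = (
                    pd.concat(frames, ignore_index=True)
                    if frames else pd.DataFrame(columns=_TRUTH_COLUMNS)
                )
                kept = truth[truth["excluded_reason"].isna()]
                n = len(kept)
                drops = sum(t.events.n_drops for t in trials)
                pct = {}
                if n:
                    n_ant = int((kept["strategy"] == ANTICIPATORY).sum())
                    pct["anticipatory_pct"] = 100.0 * n_ant / n
                    pct["confirmatory_pct"] = 100.0 * (n - n_ant) / n
                    for strat in (ANTICIPATORY, CONFIRMATORY):
                        for diff in (WITH_MARBLE, WITHOUT_MARBLE):
                            cell = kept[(kept["strategy"] == strat)
                                        & (kept["difficulty"] == diff)]
                            pct[f"{strat}_{diff}_pct"] = 100.0 * len(cell) / n
                summary.percentages = pct or None
                if drops:
                    summary.fixations_per_drop = {
                        strat: float((kept["strategy"] == strat).sum()) / drops
                        for strat in (ANTICIPATORY, CONFIRMATORY)
                    }
                dur, lead = {}, {}
                for strat in (ANTICIPATORY, CONFIRMATORY):
                    for diff in (WITH_MARBLE, WITHOUT_MARBLE):
                        cell = kept[(kept["strategy"] == strat)
                                    & (kept["difficulty"] == diff)]
                        dur[(strat, diff)] = (
                            float(cell["duration_ms"].mean()) if len(cell) else None
                        )
                        lead[(strat, diff)] = (
                            float(cell["lead_mm"].mean()) if len(cell) else None
                        )
                summary.mean_duration_ms = dur
                summary.mean_lead_mm = lead
            out.append(summary)
    return summaries_to_frame(out)


def params_to_json(params: LearningParams) -> dict:
    return asdict(params)


def params_from_json(payload: dict) -> LearningParams:
    coerced = dict(payload)
    for key in ("phase_means_first", "phase_means_final", "fix_per_segment",
                "recorded_sessions"):
        if key in coerced and coerced[key] is not None:
            coerced[key] = tuple(coerced[key])
    return LearningParams(**coerced)
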