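"""Assemble the full statistical report from per-session summaries.

The analysis plan mirrors a longitudinal motor-learning study:

* performance — repeated-measures ANOVA of session-mean MDPM across all
  training sessions, followed by all pairwise session comparisons with
  Holm-Bonferroni correction and signed effect sizes r;
* phase speed — two-tailed paired t-tests (first vs final session) for
  grasp, lift-drop and return durations, Holm-corrected as one family;
* strategy distribution — GEE (strategy x session) on the percentage
  outcomes; because the two percentages sum to 100 within a session, only
  the strategy main effect and the strategy x session interaction are
  examined; paired first-vs-final follow-up on the anticipatory share;
* visual sampling efficiency — two-way RM-ANOVA (strategy x session) on
  fixations per successful marble drop;
* associations — Spearman correlations between anticipatory share and
  MDPM at the first and final recorded sessions;
* fixation duration — three-way RM-ANOVA (strategy x difficulty x
  session);
* anticipatory lead distance — two-way RM-ANOVA (difficulty x session).

Each multiplicity family is adjusted independently and documented in the
output tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .stats import (
    EffectRow,
    effect_size_r,
    effects_to_frame,
    gee_within,
    holm_bonferroni,
    paired_t,
    rm_anova,
    spearman,
)
from .types import ANTICIPATORY, CONFIRMATORY, TRANSPORT_PHASES

_PHASE_COLS = {
    "grasp": "grasp_ms_mean",
    "liftdrop": "liftdrop_ms_mean",
    "return": "return_ms_mean",
}


@dataclass
class Report:
    tables: dict = field(default_factory=dict)
    narrative: str = ""
    errors: dict = field(default_factory=dict)  # family -> explicit reason

    def significant_families(self, alpha: float = 0.05) -> dict:
        """Per multiplicity family: does any adjusted test reject at alpha?"""
        out = {}
        for name, tab in self.tables.items():
            if "p_raw" not in tab.columns or tab.empty:
                continue
            p = tab["p_adjusted"].fillna(tab["p_raw"]) if "p_adjusted" in tab else tab["p_raw"]
            out[name] = bool((p.dropna() < alpha).any())
        return out


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InsufficientDataError(msg)


def _recorded_sessions(summaries: pd.DataFrame) -> list[int]:
    if "anticipatory_pct" not in summaries.columns:
        return []
    rec = summaries.loc[summaries["anticipatory_pct"].notna(), "session_idx"]
    return sorted(rec.unique())


def _wide(summaries: pd.DataFrame, col: str, session: int) -> pd.Series:
    sub = summaries[summaries["session_idx"] == session].sort_values("subject_id")
    return sub.set_index("subject_id")[col]


def build_report(summaries: pd.DataFrame, alpha: float = 0.05,
                 strict: bool = True) -> Report:
    """Run the full analysis plan on a tidy summary table.

    ``summaries`` has one row per subject x session (see
    :func:`toolgaze.behavior.summaries_to_frame`).  With ``strict=False``
    a gaze-derived family whose design cells are incomplete (e.g. a
    subject with no fixations in one strategy x difficulty cell) is
    reported as an explicit per-family error in ``Report.errors`` instead
    of aborting the remaining families; nothing is imputed either way.
    """
    _require(summaries["subject_id"].nunique() >= 2,
             "insufficient subjects: the statistical report needs >= 2")
    sessions = sorted(summaries["session_idx"].unique())
    _require(len(sessions) >= 2, "need >= 2 sessions")
    recorded = _recorded_sessions(summaries)
    tables: dict[str, pd.DataFrame] = {}
    lines: list[str] = []
    errors: dict[str, str] = {}

    def _family(name, fn):
        try:
            fn()
        except InsufficientDataError as exc:
            if strict:
                raise
            errors[name] = str(exc)
            lines.append(f"{name}: not computed ({exc}).")

    # ---- behavioral performance -----------------------------------------
    perf = rm_anova(summaries, dv="mdpm_mean", within=["session_idx"])
    tables["performance_anova"] = effects_to_frame(perf)
    lines.append(
        f"Training main effect on MDPM: F({perf[0].df:.0f}, {perf[0].df_denom:.0f}) "
        f"= {perf[0].stat:.3f}, p = {perf[0].p_raw:.4g}."
    )

    pair_rows = []
    for s1, s2 in itertools.combinations(sessions, 2):
        row = paired_t(
            _wide(summaries, "mdpm_mean", s1).to_numpy(),
            _wide(summaries, "mdpm_mean", s2).to_numpy(),
            effect=f"session {s1} vs {s2}",
        )
        pair_rows.append(row)
    adj = holm_bonferroni([r.p_raw for r in pair_rows])
    for r, p in zip(pair_rows, adj):
        r.p_adjusted = p
    tables["performance_pairwise"] = effects_to_frame(pair_rows)

    # ---- phase speed ------------------------------------------------------
    first_s, final_s = sessions[0], sessions[-1]

    def _phase_speed():
        speed_rows = []
        for name, col in _PHASE_COLS.items():
            speed_rows.append(
                paired_t(
                    _wide(summaries, col, first_s).to_numpy(),
                    _wide(summaries, col, final_s).to_numpy(),
                    effect=f"{name} first vs final",
                )
            )
        adj = holm_bonferroni([r.p_raw for r in speed_rows])
        for r, p in zip(speed_rows, adj):
            r.p_adjusted = p
        tables["phase_speed"] = effects_to_frame(speed_rows)
        for r in speed_rows:
            lines.append(f"{r.effect}: t({r.df:.0f}) = {r.stat:.3f}, "
                         f"Holm p = {r.p_adjusted:.4g}, r = {r.effect_size_r:.3f}.")

    _family("phase_speed", _phase_speed)

    if len(recorded) >= 2:
        rec_first, rec_final = recorded[0], recorded[-1]
        rec = summaries[summaries["session_idx"].isin([rec_first, rec_final])]

        def _distribution():
            long_pct = _melt_strategy(rec, {"anticipatory_pct": ANTICIPATORY,
                                            "confirmatory_pct": CONFIRMATORY}, "pct")
            gee_rows = gee_within(
                long_pct, dv="pct", within=["strategy", "session_idx"],
                effects=["strategy", "strategy:session_idx"],
            )
            follow = paired_t(
                _wide(rec, "anticipatory_pct", rec_first).to_numpy(),
                _wide(rec, "anticipatory_pct", rec_final).to_numpy(),
                effect="anticipatory % first vs final",
            )
            tables["distribution_gee"] = effects_to_frame(gee_rows + [follow])
            inter = next(r for r in gee_rows
                         if "strategy" in r.effect and "session_idx" in r.effect)
            lines.append(
                f"Strategy x session interaction on percentage: chi2({inter.df:.0f}) "
                f"= {inter.stat:.3f}, p = {inter.p_raw:.4g}."
            )

        def _rates():
            long_rate = _melt_strategy(rec, {"anticipatory_per_drop": ANTICIPATORY,
                                             "confirmatory_per_drop": CONFIRMATORY},
                                       "rate")
            rate_rows = rm_anova(long_rate, dv="rate",
                                 within=["strategy", "session_idx"])
            tables["fixations_per_drop_anova"] = effects_to_frame(rate_rows)

        def _associations():
            sp_rows = []
            for s in (rec_first, rec_final):
                rho, p = spearman(
                    _wide(rec, "anticipatory_pct", s).to_numpy(),
                    _wide(rec, "mdpm_mean", s).to_numpy(),
                )
                sp_rows.append(EffectRow(
                    effect=f"anticipatory % vs MDPM, session {s}",
                    stat_kind="rho", stat=rho,
                    df=len(_wide(rec, "mdpm_mean", s)) - 2, p_raw=p,
                ))
                lines.append(f"Session {s}: Spearman rho = {rho:.3f}, p = {p:.4g}.")
            tables["associations"] = effects_to_frame(sp_rows)

        def _duration():
            long_dur = _melt_cells(rec, "dur", "duration_ms")
            dur_rows = rm_anova(
                long_dur, dv="duration_ms",
                within=["strategy", "difficulty", "session_idx"],
            )
            tables["duration_anova"] = effects_to_frame(dur_rows)

        def _distance():
            long_lead = _melt_cells(rec, "lead", "lead_mm")
            long_lead = long_lead[long_lead["strategy"] == ANTICIPATORY]
            lead_rows = rm_anova(
                long_lead, dv="lead_mm", within=["difficulty", "session_idx"],
            )
            tables["distance_anova"] = effects_to_frame(lead_rows)

        _family("distribution_gee", _distribution)
        _family("fixations_per_drop_anova", _rates)
        _family("associations", _associations)
        _family("duration_anova", _duration)
        _family("distance_anova", _distance)

    # attach effect sizes to single-df F tests
    for tab in tables.values():
        if "stat_kind" in tab.columns:
            mask = (tab["stat_kind"] == "F") & (tab["df"] == 1)
            tab.loc[mask, "effect_size_r"] = [
                effect_size_r(np.sqrt(f), d)
                for f, d in zip(tab.loc[mask, "stat"], tab.loc[mask, "df_denom"])
            ]

    return Report(tables=tables, narrative="\n".join(lines), errors=errors)


def _melt_strategy(rec: pd.DataFrame, mapping: dict, value: str) -> pd.DataFrame:
    rows = []
    for col, strat in mapping.items():
        sub = rec[["subject_id", "session_idx", col]].rename(columns={col: value})
        sub = sub.assign(strategy=strat)
        rows.append(sub)
    out = pd.concat(rows, ignore_index=True)
    if out[value].isna().any():
        raise InsufficientDataError(f"missing {value} cells in the summary table")
    return out


def _melt_cells(rec: pd.DataFrame, prefix: str, value: str) -> pd.DataFrame:
    rows = []
    for strat in (ANTICIPATORY, CONFIRMATORY):
        for diff in TRANSPORT_PHASES:
            col = f"{prefix}_{strat}_{diff}"
            if col not in rec.columns:
                raise InsufficientDataError(f"summary table lacks column {col}")
            sub = rec[["subject_id", "session_idx", col]].rename(columns={col: value})
            rows.append(sub.assign(strategy=strat, difficulty=diff))
    out = pd.concat(rows, ignore_index=True)
    if out[value].isna().any():
        raise InsufficientDataError(
            f"missing {value} cells (a subject/session has no fixations in a cell)"
        )
    return out
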