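"""Statistical primitives for within-subject designs.

All tests mirror a classical repeated-measures analysis plan: univariate
repeated-measures ANOVA with unadjusted degrees of freedom (no sphericity
correction), two-tailed paired t-tests, Holm-Bonferroni step-down
familywise correction, generalized estimating equations (GEE) for
within-subject percentage outcomes, Spearman rank correlations, and the
effect size r = sqrt(t^2 / (t^2 + df)) signed by the direction of the
mean difference.

GEE model: identity link, Gaussian family, exchangeable working
correlation, with the Mancl-DeRouen bias-reduced sandwich covariance —
the plain robust sandwich is anti-conservative with only ~12 clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ToolgazeError


@dataclass
class EffectRow:
    """One line of a statistical report table."""

    effect: str
    stat_kind: str              # "F", "t", "chi2" or "rho"
    stat: float
    df: float                   # numerator df (or t df, or chi2 df)
    df_denom: Optional[float] = None
    p_raw: float = float("nan")
    p_adjusted: Optional[float] = None
    effect_size_r: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "stat_kind": self.stat_kind,
            "stat": self.stat,
            "df": self.df,
            "df_denom": self.df_denom,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "effect_size_r": self.effect_size_r,
        }


def effects_to_frame(rows: Sequence[EffectRow]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in rows])


# -- repeated measures ANOVA ------------------------------------------------


def rm_anova(
    table: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject_id",
) -> list[EffectRow]:
    """Classical within-subjects ANOVA on a complete balanced long table.

    One row per subject x cell is required; missing or duplicated cells
    raise an explicit error (no silent imputation or aggregation).
    """
    df = table[[subject, dv, *within]].copy()
    if df[dv].isna().any():
        raise InsufficientDataError(f"missing {dv} values in the ANOVA table")
    counts = df.groupby([subject, *within], observed=True).size()
    n_cells = int(np.prod([df[f].nunique() for f in within]))
    per_subject = df.groupby(subject, observed=True).size()
    if (
        counts.nunique() != 1 or counts.iloc[0] != 1
        or (per_subject != n_cells).any()
    ):
        raise InsufficientDataError(
            "ANOVA table is not complete/balanced: expected exactly one "
            "observation per subject x cell"
        )
    if df[subject].nunique() < 2:
        raise InsufficientDataError("repeated-measures ANOVA needs >= 2 subjects")
    res = AnovaRM(df, depvar=dv, subject=subject, within=list(within)).fit()
    out = []
    for effect, row in res.anova_table.iterrows():
        f = float(row["F Value"])
        p = float(row["Pr > F"])
        if not np.isfinite(f) or f < 0:
            # zero effect and zero residual variance: define F = 0, p = 1
            f, p = 0.0, 1.0
        out.append(
            EffectRow(
                effect=str(effect),
                stat_kind="F",
                stat=f,
                df=float(row["Num DF"]),
                df_denom=float(row["Den DF"]),
                p_raw=p,
            )
        )
    return out


# -- Holm-Bonferroni --------------------------------------------------------


def holm_bonferroni(p_raw: Sequence[float]) -> list[float]:
    """Step-down Holm adjustment, returned in input order."""
    p = np.asarray(list(p_raw), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ToolgazeError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="holm")
    return [float(v) for v in p_adj]


# -- paired t ---------------------------------------------------------------


def paired_t(x: Sequence[float], y: Sequence[float], effect: str = "paired") -> EffectRow:
    """Two-tailed paired-samples t-test with signed effect size r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ToolgazeError("paired_t needs two equal-length vectors")
    if len(x) < 2:
        raise InsufficientDataError("paired_t needs n >= 2")
    if np.isnan(x).any() or np.isnan(y).any():
        raise InsufficientDataError("paired_t input contains missing values")
    d = y - x
    df = len(d) - 1
    if np.allclose(d.std(ddof=1), 0.0):
        # zero-variance differences: t is 0 (all zero) or infinite
        if np.allclose(d, 0.0):
            return EffectRow(effect, "t", 0.0, df, p_raw=1.0, effect_size_r=0.0)
        sign = math.copysign(1.0, float(d.mean()))
        return EffectRow(effect, "t", sign * math.inf, df, p_raw=0.0,
                         effect_size_r=sign * 1.0)
    t, p = sps.ttest_rel(y, x)
    r = effect_size_r(float(t), df, sign=math.copysign(1.0, float(d.mean())))
    return EffectRow(effect, "t", float(t), df, p_raw=float(p), effect_size_r=r)


# -- GEE --------------------------------------------------------------------


def gee_within(
    table: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject_id",
    effects: Optional[Sequence[str]] = None,
    working_correlation: str = "exchangeable",
    cov_type: str = "bias_reduced",
) -> list[EffectRow]:
    """Marginal (GEE) model for within-subject outcomes.

    Fits ``dv ~ C(f1) * C(f2) * ...`` with subject clusters and reports a
    Wald chi-square per model term.  ``effects`` restricts the reported
    terms (matched by factor-name content, order-insensitive), e.g. to
    honor a sum-to-100 constraint that leaves only the strategy main
    effect and the strategy x session interaction identified.
    """
    df = table.copy()
    if df[dv].isna().any():
        raise InsufficientDataError(f"missing {dv} values in the GEE table")
    formula = f"{dv} ~ " + " * ".join(f"C({f})" for f in within)
    cov_struct = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
    }[working_correlation]()
    model = sm.GEE.from_formula(
        formula, groups=subject, data=df, family=sm.families.Gaussian(),
        cov_struct=cov_struct,
    )
    try:
        res = model.fit(cov_type=cov_type)
    except Exception as exc:  # non-convergence surfaces explicitly
        raise ToolgazeError(f"GEE failed to converge: {exc}") from exc

    wanted = None
    if effects is not None:
        wanted = {frozenset(e.split(":")) for e in effects}
    terms = res.wald_test_terms(scalar=True)
    out = []
    for term, row in terms.table.iterrows():
        if term == "Intercept":
            continue
        name = ":".join(
            part[2:-1] if part.startswith("C(") else part
            for part in str(term).split(":")
        )
        if wanted is not None and frozenset(name.split(":")) not in wanted:
            continue
        out.append(
            EffectRow(
                effect=name,
                stat_kind="chi2",
                stat=float(row["statistic"]),
                df=float(row["df_constraint"]),
                p_raw=float(row["pvalue"]),
            )
        )
    return out


def gee_cell_means(
    table: pd.DataFrame,
    dv: str,
    within: Sequence[str],
    subject: str = "subject_id",
    working_correlation: str = "independence",
) -> pd.DataFrame:
    """Estimated marginal cell means from the fitted GEE model."""
    df = table.copy()
    formula = f"{dv} ~ " + " * ".join(f"C({f})" for f in within)
    cov_struct = {
        "exchangeable": sm.cov_struct.Exchangeable,
        "independence": sm.cov_struct.Independence,
    }[working_correlation]()
    res = sm.GEE.from_formula(
        formula, groups=subject, data=df, family=sm.families.Gaussian(),
        cov_struct=cov_struct,
    ).fit()
    cells = df[list(within)].drop_duplicates().sort_values(list(within))
    cells = cells.reset_index(drop=True)
    cells["predicted_mean"] = res.predict(cells)
    return cells


# -- rank correlation -------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman's rho with average ranks for ties; two-tailed p.

    Returns (nan, nan) for a constant input vector (undefined, reported
    missing rather than zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InsufficientDataError("spearman needs equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


# -- effect size ------------------------------------------------------------


def effect_size_r(statistic: float, df: float, sign: float = 1.0) -> float:
    """r = sqrt(t^2 / (t^2 + df)), signed by the direction of the effect.

    Accepts a t statistic (any df) or the square root of an F(1, df)
    statistic.  Other df structures are not supported.
    """
    if df <= 0:
        raise ToolgazeError("effect_size_r needs positive denominator df")
    t2 = statistic * statistic
    if math.isinf(t2):
        return math.copysign(1.0, sign)
    return math.copysign(math.sqrt(t2 / (t2 + df)), sign)
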