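"""Statistical layer: hand oracles, classical identities, power and calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import toolgaze as tg
from toolgaze.stats import (
    effect_size_r,
    gee_cell_means,
    gee_within,
    holm_bonferroni,
    paired_t,
    rm_anova,
    spearman,
)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.03]) == [0.03]

    def test_hand_computed_step_down(self):
        # sorted (0.01, 0.03, 0.04) x (3, 2, 1) -> (0.03, 0.06, 0.04),
        # cumulative max -> (0.03, 0.06, 0.06), back in input order
        assert holm_bonferroni([0.01, 0.04, 0.03]) == pytest.approx(
            [0.03, 0.06, 0.06], abs=1e-12
        )

    def test_dominance_and_permutation_invariance(self, rng):
        for _ in range(25):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 12)))
            adj = np.asarray(holm_bonferroni(p))
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)
            perm = rng.permutation(len(p))
            adj_perm = np.asarray(holm_bonferroni(p[perm]))
            assert adj_perm == pytest.approx(adj[perm], abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(tg.ToolgazeError):
            holm_bonferroni([0.5, 1.5])


class TestPairedT:
    def test_identical_vectors(self):
        row = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert row.stat == 0.0 and row.p_raw == 1.0

    def test_hand_arithmetic(self):
        # diffs (1, 1, 2): mean 4/3, sd 1/sqrt(3), t = 4, df = 2
        row = paired_t([1, 2, 3], [2, 3, 5])
        assert row.stat == pytest.approx(4.0, abs=1e-9)
        assert row.df == 2
        assert row.p_raw == pytest.approx(2 * sps.t.sf(4.0, 2), abs=1e-12)

    def test_constant_nonzero_difference_reported_infinite(self):
        row = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert math.isinf(row.stat) and row.stat > 0
        assert row.p_raw == 0.0

    def test_power_at_study_scale_phase_effect(self, rng):
        """First-vs-final phase-speed difference detected in >= 90% of 200 runs."""
        hits = 0
        for _ in range(200):
            first = rng.normal(1750, 606, size=12)
            final = rng.normal(690, 301, size=12)
            if paired_t(first, final).p_raw < 0.05:
                hits += 1
        assert hits >= 180


class TestRmAnova:
    def _long(self, data):
        rows = []
        for i, row in enumerate(data):
            for j, v in enumerate(row):
                rows.append({"subject_id": f"s{i}", "cond": f"c{j}", "v": float(v)})
        return pd.DataFrame(rows)

    def test_identical_conditions_give_zero_f(self):
        table = self._long([[3, 3], [5, 5], [9, 9]])
        row = rm_anova(table, "v", ["cond"])[0]
        assert row.stat == 0.0 and row.p_raw == 1.0

    def test_matches_manual_sums_of_squares(self):
        data = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 9.0]])
        # manual within-subject partitioning
        gm = data.mean()
        ss_cond = data.shape[0] * ((data.mean(axis=0) - gm) ** 2).sum()
        ss_subj = data.shape[1] * ((data.mean(axis=1) - gm) ** 2).sum()
        ss_tot = ((data - gm) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        df_cond, df_err = 1, 2
        f_manual = (ss_cond / df_cond) / (ss_err / df_err)
        row = rm_anova(self._long(data), "v", ["cond"])[0]
        assert row.stat == pytest.approx(f_manual, abs=1e-9)
        assert (row.df, row.df_denom) == (1, 2)

    def test_two_condition_f_equals_paired_t_squared(self, rng):
        data = rng.normal(10, 3, size=(8, 2))
        f_row = rm_anova(self._long(data), "v", ["cond"])[0]
        t_row = paired_t(data[:, 0], data[:, 1])
        assert f_row.stat == pytest.approx(t_row.stat**2, rel=1e-9)
        assert f_row.p_raw == pytest.approx(t_row.p_raw, rel=1e-9)

    def test_missing_cell_is_explicit_error(self):
        table = self._long([[1, 2], [3, 4]]).iloc[:-1]
        with pytest.raises(tg.InsufficientDataError):
            rm_anova(table, "v", ["cond"])

    def test_session_effect_power_at_study_scale(self, rng):
        """12 x 8 log-curve tables: training effect found in >= 90% of 200 runs."""
        s = np.arange(1, 9)
        hits = 0
        for _ in range(200):
            u = rng.normal(0, 5, size=(12, 1))
            m = 14.39 + 8.946 * np.log(s) + u + rng.normal(0, 3 / np.sqrt(5), (12, 8))
            table = pd.DataFrame({
                "subject_id": np.repeat(np.arange(12), 8),
                "session": np.tile(s, 12),
                "v": m.ravel(),
            })
            if rm_anova(table, "v", ["session"])[0].p_raw < 0.05:
                hits += 1
        assert hits >= 180

    def test_cross_check_against_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        data = rng.normal(0, 1, size=(10, 4))
        rows = []
        for i in range(10):
            for a in range(2):
                for b in range(2):
                    rows.append({"subject_id": i, "A": f"a{a}", "B": f"b{b}",
                                 "v": data[i, 2 * a + b]})
        table = pd.DataFrame(rows)
        ours = {r.effect: r for r in rm_anova(table, "v", ["A", "B"])}
        theirs = pingouin.rm_anova(
            data=table, dv="v", within=["A", "B"], subject="subject_id", detailed=True,
        )
        for _, prow in theirs.iterrows():
            key = prow["Source"].replace(" * ", ":")
            assert ours[key].stat == pytest.approx(prow["F"], rel=1e-6)
            assert ours[key].p_raw == pytest.approx(prow["p_unc"], rel=1e-6)


class TestGee:
    def _table(self, values):
        rows = []
        for i, per_subject in enumerate(values):
            for (strat, sess), v in per_subject.items():
                rows.append({"subject_id": i, "strategy": strat, "session": sess,
                             "pct": v})
        return pd.DataFrame(rows)

    def test_identical_outcomes_give_zero_chi2(self):
        vals = [{(s, t): 50.0 + i for s in "ac" for t in (1, 8)} for i in range(6)]
        for row in gee_within(self._table(vals), "pct", ["strategy", "session"]):
            assert row.stat == pytest.approx(0.0, abs=1e-8)

    def test_independence_cell_means_equal_arithmetic_means(self, rng):
        vals = [{(s, t): float(rng.uniform(0, 100)) for s in "ac" for t in (1, 8)}
                for i in range(8)]
        table = self._table(vals)
        cells = gee_cell_means(table, "pct", ["strategy", "session"])
        arith = table.groupby(["strategy", "session"])["pct"].mean().reset_index()
        merged = cells.merge(arith, on=["strategy", "session"])
        assert merged["predicted_mean"].to_numpy() == pytest.approx(
            merged["pct"].to_numpy(), abs=1e-8
        )

    def test_requested_effects_only(self, rng):
        vals = [{(s, t): float(rng.uniform(0, 100)) for s in "ac" for t in (1, 8)}
                for i in range(8)]
        rows = gee_within(self._table(vals), "pct", ["strategy", "session"],
                          effects=["strategy", "strategy:session"])
        assert {r.effect for r in rows} == {"strategy", "strategy:session"}

    def test_interaction_power_at_study_scale(self, rng):
        """42 -> 56 percentage-point reversal detected in most of 200 runs."""
        hits = 0
        for _ in range(200):
            ant1 = rng.normal(42.367, 12.3, size=12)
            ant8 = rng.normal(55.761, 17.2, size=12)
            vals = [
                {("ant", 1): ant1[i], ("conf", 1): 100 - ant1[i],
                 ("ant", 8): ant8[i], ("conf", 8): 100 - ant8[i]}
                for i in range(12)
            ]
            rows = gee_within(self._table(vals), "pct", ["strategy", "session"],
                              effects=["strategy:session"])
            if rows[0].p_raw < 0.05:
                hits += 1
        assert hits > 100


class TestSpearman:
    def test_monotone_vectors(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert spearman(x, [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman(x, [40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_tied_toy_matches_hand_ranking(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        rx = np.array([1.0, 2.5, 2.5, 4.0, 5.0])  # average ranks, by hand
        ry = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        hand = (
            ((rx - rx.mean()) * (ry - ry.mean())).sum()
            / np.sqrt(((rx - rx.mean()) ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
        )
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(hand, abs=1e-12)

    def test_constant_vector_reported_missing(self):
        rho, p = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(rho) and math.isnan(p)


class TestEffectSize:
    def test_zero_statistic(self):
        assert effect_size_r(0.0, 10) == 0.0

    def test_algebraic_identity(self):
        assert effect_size_r(3.0, 9.0) == pytest.approx(math.sqrt(0.5), abs=1e-12)

    def test_sign_carries_direction(self):
        assert effect_size_r(2.0, 10, sign=-1.0) < 0

    def test_invalid_df(self):
        with pytest.raises(tg.ToolgazeError):
            effect_size_r(1.0, 0.0)
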