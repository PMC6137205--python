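"""Generator determinism, degenerate cases, and Monte-Carlo recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import toolgaze as tg
from toolgaze.synthetic import ground_truth, simulate_dataset, simulate_subject
from toolgaze.types import ANTICIPATORY, CONFIRMATORY, WITH_MARBLE, WITHOUT_MARBLE


class TestDeterminism:
    def test_same_seed_reproduces_dataset(self, default_params):
        a = simulate_subject(default_params, "S01", 99)
        b = simulate_subject(default_params, "S01", 99)
        for s in a.sessions:
            for ta, tb in zip(a.sessions[s], b.sessions[s]):
                assert ta.events.cycles == tb.events.cycles
                pd.testing.assert_frame_equal(ta.truth, tb.truth)
                if ta.gaze is not None:
                    assert ta.gaze == tb.gaze
                    assert ta.annotations == tb.annotations

    def test_plan_identical_with_and_without_materialization(self, default_params):
        a = simulate_subject(default_params, "S01", 5, materialize=True)
        b = simulate_subject(default_params, "S01", 5, materialize=False)
        for s in a.sessions:
            for ta, tb in zip(a.sessions[s], b.sessions[s]):
                assert ta.events.cycles == tb.events.cycles
                pd.testing.assert_frame_equal(ta.truth, tb.truth)


class TestDegenerateCases:
    def test_noise_free_drop_count_is_exact(self):
        params = dataclasses.replace(
            tg.LearningParams(), a=10.0, b=0.0,
            sigma_subject=0.0, sigma_trial=0.0, recorded_sessions=(),
        )
        ds = simulate_subject(params, "S01", 0, materialize=False)
        for s, trials in ds.sessions.items():
            for tr in trials:
                assert tr.events.n_drops == 10

    def test_invalid_configurations_rejected(self):
        with pytest.raises(tg.ConfigurationError):
            tg.LearningParams(trial_duration_s=0.0)
        with pytest.raises(tg.ConfigurationError):
            tg.LearningParams(n_subjects=0)
        with pytest.raises(tg.ConfigurationError):
            tg.LearningParams(b=-1.0)
        with pytest.raises(tg.ConfigurationError):
            tg.LearningParams(p_anticipatory_first=1.5)


class TestGroundTruth:
    def test_flat_curve_gives_identical_sessions(self):
        params = dataclasses.replace(tg.LearningParams(), b=0.0)
        gt = ground_truth(params)
        vals = list(gt.mdpm.values())
        assert vals == pytest.approx([vals[0]] * len(vals))

    def test_confirmatory_share_is_complement(self):
        params = dataclasses.replace(
            tg.LearningParams(), p_anticipatory_first=0.42,
            p_anticipatory_final=0.56,
        )
        gt = ground_truth(params)
        assert 1.0 - gt.p_anticipatory[1] == pytest.approx(0.58, abs=1e-12)

    def test_interpolated_share_mid_training(self):
        params = dataclasses.replace(
            tg.LearningParams(), p_anticipatory_first=0.4, p_anticipatory_final=0.6,
        )
        # hand evaluation: 0.4 + (0.6 - 0.4) * (4 - 1) / (8 - 1)
        assert params.p_anticipatory(4) == pytest.approx(0.4 + 0.2 * 3 / 7, abs=1e-12)


class TestMonteCarloRecovery:
    def test_session1_mdpm_matches_printed_anchor(self):
        """500 simulated subjects: mean session-1 MDPM within 2% of 14.217."""
        params = dataclasses.replace(
            tg.LearningParams(), a=14.2, b=7.6, n_sessions=2,
            recorded_sessions=(),
        )
        root = np.random.SeedSequence(2024)
        vals = []
        for i, child in enumerate(root.spawn(500)):
            ds = simulate_subject(params, f"S{i}", child, materialize=False)
            vals += [tg.mdpm(tr.events) for tr in ds.sessions[1]]
        assert np.mean(vals) == pytest.approx(14.217, rel=0.02)

    def test_truth_converges_to_ground_truth(self, default_params):
        """MC means of MDPM, shares, durations, leads vs analytic truth (3 SE)."""
        params = default_params
        gt = ground_truth(params)
        root = np.random.SeedSequence(7)
        n = 500
        mdpm_vals = {1: [], params.n_sessions: []}
        cells_dur = {k: [] for k in gt.duration_ms}
        cells_lead = {k: [] for k in gt.lead_mm}
        shares = {s: [] for s in params.sessions_recorded}
        for i, child in enumerate(root.spawn(n)):
            ds = simulate_subject(params, f"S{i}", child, materialize=False)
            for s in params.sessions_recorded:
                mdpm_vals[s].append(np.mean([tg.mdpm(t.events) for t in ds.sessions[s]]))
                truth = pd.concat(
                    [t.truth for t in ds.sessions[s] if len(t.truth)],
                    ignore_index=True,
                )
                kept = truth[truth.excluded_reason.isna()]
                if len(kept):  # a subject with zero drops has no fixations
                    shares[s].append((kept.strategy == ANTICIPATORY).mean())
                for strat in (ANTICIPATORY, CONFIRMATORY):
                    for diff in (WITH_MARBLE, WITHOUT_MARBLE):
                        cell = kept[(kept.strategy == strat) & (kept.difficulty == diff)]
                        if len(cell):
                            cells_dur[(strat, diff, s)].append(cell.duration_ms.mean())
                            cells_lead[(strat, diff)].append(cell.lead_mm.mean())

        def check(observed, expected):
            observed = np.asarray(observed, dtype=float)
            se = observed.std(ddof=1) / np.sqrt(len(observed))
            assert abs(observed.mean() - expected) < 3 * se + 1e-9, (
                f"mean {observed.mean():.4f} vs expected {expected:.4f} (se {se:.4f})"
            )

        for s in params.sessions_recorded:
            check(mdpm_vals[s], gt.mdpm[s])
            check(shares[s], gt.p_anticipatory[s])
        for key, vals in cells_dur.items():
            check(vals, gt.duration_ms[key])
        for key, vals in cells_lead.items():
            check(vals, gt.lead_mm[key])


class TestDetectorRecovery:
    def test_episode_agreement_at_default_noise(self, default_params):
        """>= 95% of generated fixation epochs recovered on 100 trials."""
        n_match = n_truth = 0
        n_trials = 0
        for seed in range(10):
            ds = simulate_subject(default_params, f"S{seed}", 3000 + seed)
            for s in default_params.sessions_recorded:
                for tr in ds.sessions[s]:
                    n_trials += 1
                    fx = tg.detect_fixations(tr.gaze)
                    spans = [(f.start_ms, f.end_ms) for f in fx]
                    for _, row in tr.truth.iterrows():
                        n_truth += 1
                        dur = row.end_ms - row.start_ms
                        n_match += any(
                            min(e, row.end_ms) - max(s0, row.start_ms) >= 0.5 * dur
                            for s0, e in spans
                        )
        assert n_trials == 100
        assert n_match / n_truth >= 0.95


def test_dataset_spawns_distinct_subjects(default_params):
    params = dataclasses.replace(default_params, n_subjects=3, n_sessions=2,
                                 recorded_sessions=())
    data = simulate_dataset(params, materialize=False)
    counts = [tuple(t.events.n_drops for t in ds.sessions[1]) for ds in data]
    assert len(set(counts)) > 1  # subject effects differ
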