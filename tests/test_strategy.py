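"""Transport filtering, the 36 mm rule, percentages and drop-normalized rates."""

import dataclasses

import numpy as np
import pytest

import toolgaze as tg
from toolgaze.strategy import (
    NO_TIP,
    NOT_TRANSPORT,
    OFF_SETUP,
    classify,
    classify_session,
    classify_trial,
    filter_fixation,
    fixations_per_drop,
    strategy_percentages,
)
from toolgaze.types import (
    ANTICIPATORY,
    CONFIRMATORY,
    OTHER,
    WITH_MARBLE,
    WITHOUT_MARBLE,
    Cycle,
    FrameAnnotation,
    Point,
    TrialEvents,
)


def fix(centroid=(600.0, 500.0), start=0, end=100):
    return tg.Fixation(start_ms=start, end_ms=end, centroid=centroid,
                       dispersion_px=10.0, n_samples=4)


def ann(phase=WITH_MARBLE, tip=(600.0, 520.0), in_setup=True, t=50):
    return FrameAnnotation(
        t=t, cyl_base=Point(600.0, 700.0), cyl_apex=Point(600.0, 400.0),
        tip=Point(*tip) if tip else None, phase=phase, in_setup=in_setup,
    )


ROI = (0.0, 0.0, 1280.0, 960.0)


class TestClassifyThreshold:
    def test_boundary_is_confirmatory(self):
        assert classify(36.0) == CONFIRMATORY

    def test_just_above_is_anticipatory(self):
        assert classify(36.1) == ANTICIPATORY

    def test_negative_lead_is_confirmatory(self):
        assert classify(-10.0) == CONFIRMATORY

    def test_threshold_sweep(self):
        for lead in np.arange(35.90, 36.10, 0.001):
            expected = ANTICIPATORY if lead > 36.0 else CONFIRMATORY
            assert classify(float(lead)) == expected


class TestFilter:
    def test_non_transport_phase_removed(self):
        assert filter_fixation(fix(), ann(phase=OTHER), ROI) == NOT_TRANSPORT

    def test_centroid_outside_setup_removed(self):
        assert filter_fixation(fix(centroid=(2000.0, 500.0)), ann(), ROI) == OFF_SETUP

    def test_kept_when_transport_in_roi_with_tip(self):
        assert filter_fixation(fix(), ann(), ROI) is None

    def test_missing_tip_removed(self):
        assert filter_fixation(fix(), ann(tip=None), ROI) == NO_TIP

    def test_transport_check_takes_precedence(self):
        reason = filter_fixation(fix(centroid=(2000.0, 500.0)), ann(phase=OTHER), ROI)
        assert reason == NOT_TRANSPORT


class TestPercentages:
    def _classified(self, labels):
        return [
            tg.ClassifiedFixation(fixation=fix(), lead_mm=0.0, strategy=s,
                                  difficulty=d)
            for s, d in labels
        ]

    def test_three_to_one_split(self):
        labels = [(ANTICIPATORY, WITH_MARBLE)] * 3 + [(CONFIRMATORY, WITH_MARBLE)]
        pct = strategy_percentages(self._classified(labels))
        assert pct["anticipatory_pct"] == 75.0
        assert pct["confirmatory_pct"] == 25.0

    def test_four_equal_cells(self):
        labels = [(s, d) for s in (ANTICIPATORY, CONFIRMATORY)
                  for d in (WITH_MARBLE, WITHOUT_MARBLE)]
        pct = strategy_percentages(self._classified(labels))
        for s, d in labels:
            assert pct[f"{s}_{d}_pct"] == 25.0

    def test_cells_sum_to_100(self, rng):
        for _ in range(20):
            labels = [
                (rng.choice([ANTICIPATORY, CONFIRMATORY]),
                 rng.choice([WITH_MARBLE, WITHOUT_MARBLE]))
                for _ in range(int(rng.integers(1, 40)))
            ]
            pct = strategy_percentages(self._classified(labels))
            assert pct["anticipatory_pct"] + pct["confirmatory_pct"] == pytest.approx(100, abs=1e-9)
            four = sum(pct[f"{s}_{d}_pct"] for s in (ANTICIPATORY, CONFIRMATORY)
                       for d in (WITH_MARBLE, WITHOUT_MARBLE))
            assert four == pytest.approx(100.0, abs=1e-9)

    def test_zero_fixations_reported_missing(self):
        pct = strategy_percentages([])
        assert pct["anticipatory_pct"] is None
        assert pct["confirmatory_pct"] is None


class TestFixationsPerDrop:
    def _events(self, n_drops):
        cycles = [Cycle(2000 * i, 2000 * i + 500, 2000 * i + 1000, 2000 * i + 1500)
                  for i in range(n_drops)]
        return TrialEvents(trial_start=0, trial_end=60000, cycles=cycles)

    def test_rate(self):
        cls = [tg.ClassifiedFixation(fixation=fix(), lead_mm=0.0,
                                     strategy=CONFIRMATORY, difficulty=WITH_MARBLE)
               for _ in range(30)]
        rates = fixations_per_drop(cls, [self._events(20)])
        assert rates[CONFIRMATORY] == 1.5
        assert rates[ANTICIPATORY] == 0.0

    def test_zero_drops_missing_value(self):
        rates = fixations_per_drop([], [self._events(0)])
        assert rates[ANTICIPATORY] is None


class TestSessionClassification:
    def test_counts_conserved_on_synthetic_trial(self, one_subject, config):
        tr = one_subject.sessions[1][0]
        fx = tg.detect_fixations(tr.gaze)
        cls = classify_trial(fx, tr.annotations, config, tr.trial_id)
        assert len(cls) == len(fx)
        kept = sum(c.kept for c in cls)
        excluded = sum(not c.kept for c in cls)
        assert kept + excluded == len(fx)
        for c in cls:
            if c.kept:
                assert c.exclusion_reason is None and c.strategy is not None
            else:
                assert c.strategy is None and c.difficulty is None

    def test_all_other_phases_excludes_everything(self, config):
        frames = [ann(phase=OTHER, t=t) for t in range(0, 2000, 33)]
        fixations = [fix(start=200, end=400), fix(start=900, end=1100)]
        cls = classify_trial(fixations, frames, config)
        assert all(c.exclusion_reason == NOT_TRANSPORT for c in cls)

    def test_disjoint_time_ranges_raise_alignment_error(self, config):
        frames = [ann(t=t) for t in range(0, 300, 33)]
        fixations = [fix(start=5000, end=5400)]
        ev = TrialEvents(trial_start=0, trial_end=60000)
        with pytest.raises(tg.AlignmentError):
            classify_session([(fixations, frames, ev)], config)

    def test_generated_strategy_share_recovered(self, config):
        """p_anticipatory = 0.6 -> observed share within 3 binomial SE."""
        params = dataclasses.replace(
            tg.LearningParams(), p_anticipatory_first=0.6, p_anticipatory_final=0.6,
            n_sessions=1, recorded_sessions=(1,),
        )
        ds = tg.simulate_subject(params, "S01", 77)
        kept = []
        for tr in ds.sessions[1]:
            fx = tg.detect_fixations(tr.gaze)
            kept += [c for c in classify_trial(fx, tr.annotations, config) if c.kept]
        share = np.mean([c.strategy == ANTICIPATORY for c in kept])
        se = np.sqrt(0.6 * 0.4 / len(kept))
        assert abs(share - 0.6) < 3 * se + 1e-12

    def test_generated_fixation_rate_recovered(self, config):
        """1.2 anticipatory fixations per cycle by construction (ample segments)."""
        params = dataclasses.replace(
            tg.LearningParams(),
            a=8.0, b=0.0, sigma_subject=0.0, sigma_trial=0.0,
            p_anticipatory_first=0.4, p_anticipatory_final=0.4,
            fix_per_segment=(1, 2),          # mean 1.5 per segment, 3 per cycle
            phase_means_first=(2000.0, 2600.0, 2600.0),
            phase_means_final=(2000.0, 2600.0, 2600.0),
            mu_dur_conf_first=180.0, mu_dur_conf_final=180.0, mu_dur_ant=180.0,
            sigma_dur=20.0, p_grasp_fixation=0.0, p_tip_missing=0.0,
            n_sessions=1, recorded_sessions=(1,), n_trials_per_session=5,
        )
        per_trial = []
        for seed in range(6):
            ds = tg.simulate_subject(params, f"S{seed}", 1000 + seed)
            for tr in ds.sessions[1]:
                fx = tg.detect_fixations(tr.gaze)
                cls = classify_trial(fx, tr.annotations, config)
                n_ant = sum(c.kept and c.strategy == ANTICIPATORY for c in cls)
                per_trial.append(n_ant / tr.events.n_drops)
        rate = np.mean(per_trial)
        se = np.std(per_trial, ddof=1) / np.sqrt(len(per_trial))
        assert abs(rate - 1.2) < 3 * se
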