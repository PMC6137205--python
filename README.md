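# toolgaze

Analysis pipeline for eye–hand coordination during tool-use motor
learning. The target experiment: subjects naïve to chopsticks practice
grasping marbles and dropping them into a cylindrical container over
eight training sessions (five analyzed 60 s trials per session), wearing
a head-mounted eye tracker (30 Hz scene camera, 1280 × 960 px) during the
first and final sessions. The package is for researchers who have (or
want to simulate) three per-trial input streams — gaze samples, per-frame
scene annotations (cylinder endpoints, chopstick tip, movement phase) and
trial event logs — and want the behavioral and gaze statistics of such a
longitudinal design reproducibly, from raw delimited files to report
tables.

## What it computes

**Behavioral performance.** MDPM (successful marble drops per minute) per
trial; phase speeds (time to grasp, time to lift-and-drop, time to
return); and the logarithmic practice curve

```
MDPM(s) = a + b·ln(s),   s = 1…8 (session index)
```

fit by OLS to session means, the classic signature of motor skill
acquisition.

**Fixation detection (I-DT).** A fixation is a maximal sample window whose
dispersion `(max x − min x) + (max y − min y)` stays ≤ 100 px for
≥ 80 ms (both configurable), found by the standard greedy
dispersion-threshold scan. Short tracking dropouts (≤ 2 samples) are
bridged by interpolation; longer ones break the window.

**Cylinder-referenced geometry.** The container of known physical length
seen in every frame fixes the mm/px scale and the movement axis, so the
signed lead of the fixation over the chopstick tip,

```
lead = ⟨fix − tip, g⟩ · mm_per_px,   g = ±(apex − base)/‖apex − base‖
```

(+ toward the apex while carrying the marble, + toward the base on the
return), is invariant to the observer's head pose — any rotation,
translation or uniform scaling of the scene.

**Strategy classification.** Transport-phase fixations are *anticipatory*
if they lead the tip by more than 36 mm — a threshold derived from the
apparatus: (4 mm tip diameter + 8 mm marble radius) × 3 for detector
dispersion — and *confirmatory* otherwise; each is further split by
movement difficulty (with vs without the marble). Non-transport,
off-setup and tip-occluded fixations are excluded, each with a logged
reason, and counts are conserved.

**Statistics.** Repeated-measures ANOVAs (uncorrected df), Holm–Bonferroni
pairwise families, paired t-tests, GEE (Gaussian, identity link,
exchangeable working correlation, small-sample bias-reduced sandwich
covariance) for the sum-to-100 percentage outcomes, Spearman
correlations, and effect sizes r = √(t²/(t²+df)).

**Synthetic data.** A first-class generator emulates the full study —
logarithmic learning with subject and trial noise, drop-cycle event logs,
fixation schedules with session-interpolated anticipatory probability,
scatter-separated gaze samples, per-trial head-pose transforms — with
closed-form ground truth for every estimated quantity
(`toolgaze.ground_truth`).

## Worked example

```python
import toolgaze as tg

params = tg.LearningParams()          # the 12-subject, 8-session design
config = tg.RunConfig(cylinder_physical_length_mm=params.cylinder_length_mm)
tg.run_pipeline(config, "study_out", sim_params=params, seed=1)
```

or equivalently `toolgaze run --simulate --seed 1 --out study_out`. This
writes the raw delimited files, re-reads them through the same parsers
real data would use, detects and classifies every fixation, and emits
`summaries.csv`, `classified_fixations.csv`, `learning_curve.json`,
`report/*.csv`, `report/narrative.txt` and a checksummed `manifest.json`.
With seed 1 it prints/stores:

```
MDPM session 1 -> 8: 12.28 -> 31.80
log curve: a=12.34, b=9.34, r2=0.999
anticipatory %: 43.2 -> 55.6
Training main effect on MDPM: F(7, 77) = 300.276, p = 3.628e-53.
grasp first vs final: t(11) = -5.193, Holm p = 0.0008926, r = -0.843.
Strategy x session interaction on percentage: chi2(1) = 94.383, p = 2.6e-22.
```

Reading: performance rises from ~12 to ~32 drops/min along an almost
perfect log curve; grasping gets faster; and the strategy distribution
reverses from confirmatory-dominant (43% anticipatory) to
anticipatory-dominant (56%) — the qualitative fingerprint of motor
learning in this task. Real recordings run through the same command with
`--gaze/--annot/--events` (single trial) or `--index` (a trial manifest);
file schemas are documented in `docs/formats.md`, the model and its
assumptions in `docs/methods.md`.

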