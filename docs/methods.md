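# Methods

## The task and the measurement model

The pipeline analyzes a longitudinal tool-use learning experiment:
repeated 60 s trials of grasping a marble with chopsticks, carrying it to
the apex of a cylindrical container, dropping it, and returning to the
base. Behavior is summarized per trial as successful drops per minute
(MDPM) and per drop cycle as three phase durations (grasp = grasp onset →
secure grasp; lift-drop = secure grasp → drop into the cylinder; return =
drop → arrival back at the base). Skill acquisition is modeled as a
logarithmic practice curve, `MDPM(s) = a + b·ln(s)` with 1-based session
index, fit by ordinary least squares to session means; `r²` is reported
but the curve is descriptive, not inferential.

Gaze is analyzed only for the sessions with eye-tracking recordings (the
first and final sessions in the emulated design). Fixations come from the
dispersion-threshold (I-DT) algorithm; each fixation is matched to the
scene frame nearest its temporal midpoint (ties to the earlier frame, the
least biased single-frame choice), filtered to transport phases inside
the setup region, and classified as anticipatory or confirmatory by its
signed lead over the chopstick tip along the cylinder axis.

### Why the cylinder is the reference

Scene-camera pixels conflate gaze behavior with head pose: sitting closer
magnifies the scene, tilting the head rotates it. Since the cylinder's
physical length is fixed, its per-frame image determines both the mm/px
scale and the movement axis, making the lead distance invariant under any
similarity transform of the image. "Vertical" distance is therefore
implemented as the along-axis component, not image-vertical — slope
correction only matters if distance lives in the cylinder's frame. The
physical cylinder length is a required configuration value with no
default; nothing in the analysis can recover it from images alone.

### Sign convention and the goal direction

The goal direction flips with the movement phase: toward the apex while
carrying the marble, toward the base on the return. This reading follows
from the task's two movement goals — a gaze point can only "lead" the
tool relative to where the tool is going. A consequence is antisymmetry:
relabeling the phase negates the lead. Whether the original procedure
used signed or absolute distances is not documented; the signed version
is strictly more informative and reduces to the absolute one under the
classification rule (a fixation trailing the tip can never exceed a
positive threshold).

### The 36 mm threshold

Derived from apparatus geometry: (4 mm chopstick-tip diameter + 8 mm
marble radius) × 3, the factor covering the spatial slack the dispersion
detector tolerates. The boundary is exact: lead ≤ 36 mm is confirmatory,
> 36 mm anticipatory. The threshold is applied in physical millimetres.
Published cell means for anticipatory lead distances (≈ 7–10) sit below
this threshold, which is unit-inconsistent on its face; this package
makes no attempt to reconcile that and reports leads in mm under its own
convention (see Limitations).

## Fixation detection

Classic I-DT with dispersion = (x-range + y-range) of the sample window;
defaults 100 px maximum dispersion, 80 ms minimum duration at 30 Hz.
The exact scheme: seed the smallest window spanning the minimum duration;
if its dispersion is within threshold, extend right until the next sample
would violate it, emit, and resume after the window; otherwise slide the
start by one sample. Duration is measured first-to-last sample timestamp,
the centroid is the arithmetic sample mean, and ties cannot arise under
greedy maximal extension. At 30 Hz the duration minimum implies ≥ 4
samples per fixation. Invalid samples: interior runs of ≤ 2 samples are
linearly interpolated (logged); longer runs split the stream. No
post-hoc merging of nearby fixations is performed; commercial event
detectors may merge, which is a known source of divergence. A naive
full-rescan reference implementation (`toolgaze.reference`) serves as the
equivalence oracle in the test suite.

## Statistics

* Repeated-measures ANOVA with classical within-subject partitioning and
  *unadjusted* degrees of freedom (no sphericity correction), matching
  the conventional reporting style of this literature. Incomplete or
  unbalanced tables are an explicit error; nothing is imputed.
* All 28 pairwise session comparisons form one Holm–Bonferroni family;
  the three phase-speed t-tests form another.
* Strategy percentages sum to 100 within a session, so the percentage
  GEE examines only the strategy main effect and the strategy × session
  interaction. The GEE uses a Gaussian family with identity link and
  exchangeable working correlation — percentages are continuous bounded
  outcomes and the reported statistics are Wald χ² — with the
  Mancl–DeRouen bias-reduced sandwich covariance, because the plain
  robust sandwich is anti-conservative with ~12 clusters. Null
  simulations in the acceptance suite confirm the headline test's type-I
  error sits inside the binomial 95% interval of α = 0.05.
* Effect size: r = √(t²/(t²+df)), signed by the direction of the mean
  difference; also applied to F(1, ·) effects via √F. Other df
  structures are flagged, not converted.
* Spearman correlations use average ranks for ties; a constant input is
  reported missing, never as zero correlation.
* `build_report` runs the full plan; with `strict=False` a gaze-derived
  family whose design cells are empty (e.g. a subject with no
  anticipatory fixations in one cell) is recorded as an explicit
  per-family error while the remaining families complete.

## The synthetic-data generator

The generator is first-class, tested code: it is the only way to exercise
the full pipeline end to end, since datasets of this kind are not
publicly deposited.

Generating model, per trial:

1. **Drop count.** `k = round(max(0, a + b·ln(s) + u_subject + e_trial))`
   with `u ~ N(0, σ_subject²)`, `e ~ N(0, σ_trial²)`. Defaults
   `a = 14.390`, `b = 8.946` are the OLS fit of published session-mean
   anchors on ln(s); `σ_subject = 5.0` matches the reported
   between-subject SEM at n = 12; `σ_trial = 3.0` is a free choice (no
   trial-level variance is published) and is the one generator constant
   not anchored to printed data.
2. **Cycle layout.** Phase durations draw around session means that
   interpolate log-linearly between first-session (1750/748/1006 ms) and
   final-session (690/449/606 ms) anchors, scaled by the trial's speed
   factor (fast trials are proportionally faster in every phase) and
   divided by an analytic normalization `E[ā/max(m,1)]` so per-trial mean
   phase durations stay unbiased. Cycles are laid sequentially with the
   remaining slack distributed as random gaps; integer-millisecond
   rounding reserves headroom so event times never leave the trial.
3. **Fixation schedule.** Each cycle's two transport segments get 1–3
   fixations; strategy is Bernoulli with the anticipatory probability
   interpolated linearly from 0.42367 (session 1) to 0.55761 (final
   session); durations are Gaussian (anticipatory 206.6 ms
   training-invariant; confirmatory 208.6 → 166.5 ms across training;
   +25 ms when moving without the marble; σ = 40 ms), quantized to the
   30 Hz grid with a 4-sample floor. A fixation belongs to the segment
   containing its temporal midpoint and may spill past the boundary, as
   real fixations straddle phase transitions; the room check before each
   draw uses the worst-case fixation length of the cell — never the
   strategy actually drawn — so short segments thin counts without
   biasing the strategy mix or per-cell distributions.
4. **Leads.** Anticipatory leads are truncated normals (mean 55 mm with
   marble, 65 mm without, σ = 8) bounded below at 38 mm; confirmatory
   leads are truncated normals (mean 12, σ = 10) bounded above at 34 mm.
   The 2 mm guard bands around the 36 mm rule keep the intended labels
   recoverable despite centroid jitter. The published anticipatory
   distance means (6.857/9.654) cannot exceed the threshold that defines
   anticipatory fixations, so they cannot serve as generating means in
   mm; the defaults instead preserve their ordering (without > with) at
   threshold-consistent magnitudes.
5. **Gaze samples.** Fixation samples are the intended point plus
   isotropic 3 px jitter (clipped at 3.5σ); between fixations, 2–4
   scatter samples with consecutive L1 displacements ≥ 160 px guarantee
   the detector separates adjacent fixations. Each trial is viewed
   through a random similarity transform (±15° rotation, 0.9–1.1 scale,
   ±20 px translation) emulating head pose; leads are invariant to it by
   construction. The canonical cylinder is 300 px long and 150 mm
   physically (an ordinary container length; only the ratio matters).
6. **Auxiliary structure.** With probability 0.1 per cycle a grasp-phase
   fixation exercises the `not_transport` exclusion; 2% of transport
   frames omit the tip annotation, exercising `no_tip`.

`ground_truth` returns closed-form expectations for every estimated
quantity — `E[round(max(N,0))]` for MDPM, interpolated proportions,
quantized-Gaussian means for durations, truncated-normal means for leads,
interpolated phase means — and the test suite verifies Monte-Carlo
convergence at 500 subjects within three standard errors, plus ≥ 95%
episode-level recovery of the schedule through the real detector.

### What the generator does not emulate

Oculomotor realism (main-sequence saccade dynamics, microsaccades, smooth
pursuit, pupil size), arm kinematics, camera optics (lens distortion, 3-D
perspective), annotation error in the cylinder/tip points, and any
subject-level coupling between anticipatory share and performance —
strategy draws are independent of the subject's skill, so the
positive anticipatory-performance correlations seen in real data are
*not* built in and the report's Spearman rows on synthetic data hover
near zero. Passing tests therefore demonstrate the pipeline's
correctness and calibration, not that real gaze data will look like the
simulation.

## Numerical choices

* Timestamps are integer milliseconds, 0-based per trial
  (`t_i = ⌊1000·i/30⌋`), avoiding float drift; 80 ms at 30 Hz then means
  ≥ 4 samples and the published-style ~33 ms quantization of durations.
* Problem sizes in the acceptance layer — 1,000 oracle streams, 10,000
  invariance configurations, 200 recovery and 200 null replicates (the
  replicate loops run the planner without rendering pixel streams) — are
  the package's chosen balance of statistical resolution against a
  single-CPU run of a few minutes.
* Dispersion comparisons use `≤` on the raw float values; the detector's
  incremental min/max updates are exactly equivalent to full re-scans
  (asserted against the reference).
* Zero-variance degenerate inputs are defined, not NaN: paired t on
  identical vectors is (t = 0, p = 1), on constant nonzero differences
  (±∞, p = 0); an ANOVA effect with zero numerator and residual SS is
  (F = 0, p = 1).

## Limitations

* The anticipatory/confirmatory distinction reduces a continuous lead to
  a hard threshold; measurement noise near 36 mm flips labels, which the
  generator sidesteps with guard bands but real data will not.
* The published distance-unit inconsistency (anticipatory distance means
  below the anticipatory threshold) is documented, not resolved; lead
  magnitudes from this pipeline are not directly comparable to those
  figures.
* Effect sizes of the form r = √(t²/(t²+df)) cannot reproduce some
  published values (e.g. near-zero r alongside p < 0.001); the formula
  is reported as implemented and the discrepancy left standing.
* GEE Wald tests at 12 clusters remain approximate even with the
  bias-reduced covariance; exact small-sample inference is out of scope.
* No sphericity correction is offered; with 8 repeated sessions the
  uncorrected F is liberal under non-sphericity.
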