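# Methods

This note documents the models, conventions and numerical choices behind
`coordkin`, in the order the pipeline uses them.

## Data model and conventions

Recordings are intrinsic Tait–Bryan pitch/roll/yaw angles in degrees on
a uniform time grid with the nominal 68 ms sample period (0.068 s),
zeroed at the participant's self-selected neutral pose. The sign
convention is: pitch + = flexion (down-steer), roll + = right lateral
flexion, yaw + = right axial rotation. Acquisition devices rarely state
their Euler order; the package treats the order as a convention and
applies it consistently rather than claiming it matches any specific
hardware. Irregular grids are linearly resampled on read (exact for
affine signals, endpoints preserved) and flagged in the metadata.
Canonical storage is a plain CSV plus a JSON sidecar: for small
kinematic datasets, inspectability beats binary containers.

## Course geometry

Coins are 58 m apart and flown at a constant 12 m/s. The ideal path is a
**centripetal** Catmull–Rom spline (α = 0.5) through the coins, with
phantom-point reflection at the ends; the centripetal variant is chosen
because it cannot cusp or self-intersect on turn sequences, which the
uniform variant can. The coin plane is perpendicular to the ideal-path
tangent at the coin (not to the instantaneous flight direction);
steering error is the in-plane Euclidean distance from the linearly
interpolated plane-crossing point to the coin center, with a `'3d'`
option exposed. A trajectory that never crosses a plane is flagged
`missed` and its error is taken at the closest approach to the plane;
downstream averaging includes missed coins by default since excluding
them would reward giving up on a coin.

## Segmentation and the feature battery

Sequences are split at the interpolated plane-crossing times, one
segment per consecutive coin pair. A segment is rejected when any
consecutive-sample angular change on any axis of either segment trace
*strictly* exceeds 20° (a change of exactly 20.0° is kept); this is the
IMU-interference artifact rule, and on clean synthetic data it fires
zero times.

Per-variable conventions, where the generic definition leaves room:

* **Amplitude**: interquartile range with linear-interpolation
  (type-7) quantiles.
* **Speeds**: finite differences |Δθ|/Δt; the norm is the per-sample
  Euclidean norm of the three axis rates.
* **Correlations** are computed on angle positions (a rate-based
  option exists) and reported as absolute values.
* **Cross-correlation peak lag** uses Pearson normalization per lag,
  bounded at ± half the segment length to avoid spurious edge peaks;
  negative lags mean the head leads the torso.
* **DTW**: both traces linearly resampled to 64 points, unconstrained
  warping, absolute-difference local cost, symmetric steps; implemented
  as a vectorized anti-diagonal (wavefront) dynamic program and verified
  against an exhaustive top-down oracle.
* **SAL**: zero-padding to the next power of two times 2⁴, magnitude
  spectrum normalized by DC, arc length up to a 10 Hz cutoff with an
  adaptive 0.05 amplitude threshold, frequency axis normalized by the
  cutoff actually used. Computed per torso axis on the |rate| profile.
* **Peak counts**: `scipy.signal.find_peaks` with a 1° prominence
  threshold (above sensor noise, configurable), divided by segment
  duration. "Bird" peaks are computed on the flight heading angles
  (elevation → pitch, azimuth → yaw; the kinematic avatar has no roll),
  with a position-derivative option.
* **Speed ratio**: mean/max |rate|; a perfectly constant rate returns
  exactly 1 by definition to avoid float-summation noise.

Two of the battery's row ranges name one quantity across three slots;
the package resolves them as: steering error summarized as
{mean, median, max} over segments, and SAL per torso axis. Per-segment
values are arithmetic-mean averaged over the sequence; undefined values
(e.g. a correlation on a flat trace) are skipped, not zero-filled, which
would bias averages toward null values. The path ratio is computed once
for the whole sequence. The anchoring index is computed per segment for
flight sequences and over the whole trial for JAR trials.

## PCA variable selection

The feature table is z-scored per column (sample SD, ddof = 1; constant
columns dropped with a report). Outliers are observations whose
Euclidean distance to the centroid exceeds the mean distance by more
than 4 SDs **of the distance distribution**; they receive weight 0.5.
The weighted PCA eigendecomposes
`C = Σ wᵢ (zᵢ − μ_w)(zᵢ − μ_w)ᵀ / Σ wᵢ` with the weighted mean `μ_w`;
components are ordered by decreasing eigenvalue with a deterministic
sign convention (largest-magnitude loading positive), and numerically
null directions (eigenvalue < 1e-12 of the trace) are dropped.
"Normalized loadings" are each component's loadings divided by that
component's maximum absolute loading, so the 0.75 threshold is
scale-free; an alternative normalization (raw unit-norm entries) is a
one-line substitution via `PcaResult.normalized_loadings`. Outlier
weights are recomputed per analysis subset (all / head-only /
torso-only), since each subset has its own centroid. Functional
clustering of the selected variables is metadata-driven: every variable
carries an a-priori category tag (torso movements, head movements,
head–torso coordination, steering error) and clusters are the selected
set partitioned by tag — the grouping reflects meaning, not an
algorithm.

## Statistics

Each response is screened with the Anderson–Darling test at the fixed
5% critical value; on rejection it is shifted to be strictly positive
(shift recorded) and Box–Cox transformed with the maximum-likelihood λ.
The transformation applies to the response of each analysis as a whole,
not per cell.

The mixed repeated-measures ANOVA is the classical split-plot
decomposition on the complete subject × within-cells cube: one optional
between-subjects factor (groups may be unequal; group-size-weighted
sums of squares) and one or two within-subject factors; replicates
within a cell are averaged and subjects with missing cells are dropped
listwise. Error terms are subjects-within-groups for between effects
and the factor × subjects-within-groups interactions for within
effects; partial η² = SS_effect / (SS_effect + SS_error). No sphericity
correction is applied by default (an option hook exists); with
two-level within factors the question does not arise. The
implementation is validated against a cell-totals hand oracle,
pingouin's `mixed_anova` and statsmodels' `AnovaRM`, and its null
type-I rate is calibrated at 10,000 replicates.

TSBKY FDR: stage 1 is a Benjamini–Hochberg step-up at
α′ = α/(1+α) estimating m₀ = m − r₁; stage 2 reruns the step-up at
α′·m/m₀ (r₁ = 0 rejects nothing, r₁ = m everything). The family over
which FDR is controlled is always an explicit argument — the package
never guesses a family.

## JAR metrics

The final orientation is the mean of the tested body part's steering
angle over the samples in the last 1.5 s of the trial (closed boundary
on the sample grid — the last 23 samples of a 4 s trial at 68 ms; an
interpolated-boundary variant agrees within 0.05° on smooth traces).
The measured "steering angle" for the ±15° lateral targets is the same
linear combination of roll and yaw the flight game uses for turns
(weights 0.5/0.5), with single-axis options. Signed error is
final − target (positive = beyond the target for positive targets;
mirrored pooling flips −15° trials). Overshoot is the maximum excursion
beyond the target in the target's direction, 0 if never beyond.
Oscillations are counted as sign changes of (angle − final) after the
trace first enters a ±1° band around the final angle — the quantity is
conventionally named but nowhere standard, so the band is a package
convention. For torso trials the head anchoring index (whole trial),
final head−torso difference and head alignment error
(final head − target; negative = head short of the torso) are added.

## The synthetic generator

The generator is kinematic, not biomechanical — no masses or inertias;
its purpose is to exercise every downstream statistic with known ground
truth, not to model physiology. Four parameters map onto the scientific
constructs: coupling c ∈ [0,1] (fraction of head motion riding on the
torso; 1 = en-bloc), overshoot gain g > 0 (executed amplitude per unit
intended; g > 1 models proprioceptive overestimation), compensatory
head gain h ≥ 0 (instantaneous proportional opposition −h·torso; a
lagged variant is off by default), and measurement noise SD in degrees.

Flight trials run a closed steering loop at the 68 ms step: every 0.5 s
(intermittent human corrections) the aim point is the next uncrossed
coin plus Gaussian scatter of 2 m per degree of noise SD; the commanded
controller angle is 1.5°/° of heading error, clipped at 40°; the
executed angle tracks g × command through a first-order lag (default
τ = 0.3 s) with a 120°/s rate cap; heading integrates 1°/s per degree
of the lateral (roll+yaw)/2 combination and of pitch; position advances
at 12 m/s. Holding commands between replans is what lets the amplitude
bias survive: with continuous feedback a multiplicative gain cancels at
the loop's fixed point, and crossing error would not grow with g. With
g = 1, zero noise and a short lag the loop flies through the coin
centers (mean error < 5 cm, path ratio ≈ 1); crossing error increases
monotonically in g at fixed noise. The head trace mixes
(c − h)·torso + (1 − c)·gaze + noise, where the gaze surrogate is
Gaussian-kernel-smoothed white noise (0.5 s kernel, 5° SD) — real gaze
has task-locked structure this does not capture.

JAR trials follow a slightly underdamped second-order step response
(ωₙ = 4 rad/s, ζ = 0.65, ≈ 7% transient overshoot) toward
g_eff × target, with g_eff = 1 under visual feedback and g otherwise,
plus noise; the torso-trial head trace is (c − h)·torso + noise.

Cohorts reproduce the study-like protocol: per participant and control
body part, sequences of 26/50/50/18/26 coins (phases Before, Training,
Training, After, DayAfter) and a JAR protocol of 5/10/10 repetitions
per target for Feedback/NoFeedback/Forward; group sizes default to
9/12/11/13 (6 y.o., 8–9 y.o., 10 y.o., adults). Group priors express
the developmental narrative as defaults — young groups couple less
(c: 0.45 → 0.90 with age), overestimate more (g: 1.5 → 1.02),
compensate more (h: 0.35 → 0.05) and are noisier (1.0° → 0.5°) — with
per-participant truncated-normal draws (SDs 0.08/0.08/0.05/0.1). These
encode ordering and plausible magnitudes, not fitted human values.

Parameter recovery estimates c per participant from the mean head–torso
roll–roll and yaw–yaw absolute correlations of torso-controlled
sequences (both axes carry the lateral steering signal, so pooling
halves estimator noise) and g from 1 + signed error/target in
no-feedback JAR trials; recovery quality is reported as Spearman rank
correlation because the estimators are monotone in, not equal to, the
parameters.

## Problem sizes and determinism

Everything is seeded through `numpy.random.SeedSequence`; identical
configurations are bit-for-bit reproducible, and the PCA sign
convention makes the whole chain deterministic. Tests and the
acceptance script use scaled cohorts — 12 participants, 8-coin
sequences, reduced JAR repetitions — which exercise every code path at
a few percent of the full protocol's cost; the full 26/50/50/18/26
protocol remains the cohort default. The acceptance script's recovery
sweep uses 20 replicate cohorts pooled (240 participants), the ANOVA
null calibration 10,000 replicates, and the anchoring-index Monte Carlo
10⁵ samples.

## What passing tests do and do not show

The generator shares the pipeline's angle conventions and produces
exactly the artifact types the rejection rule targets, so green tests
demonstrate internal consistency, correct mathematics (against
independent oracles: exhaustive DTW, plain eigendecomposition,
cell-total ANOVA sums of squares, manual TSBKY traces, permutation
tests) and recoverability of coordination structure at realistic noise.
They do not certify hardware-specific artifacts (drift, magnetic
disturbance signatures), real gaze dynamics, or the biomechanics of
actual children — claims about human data still require human data.

## Known limitations

* The rm-ANOVA supports at most two within-subject factors and one
  between factor, without sphericity correction — adequate for the
  designs at hand, not a general ANOVA engine.
* The flight simulator's steering map (proportional heading control
  with a fixed roll/yaw split) is one of many plausible inversions of
  the game's "linear combination" description.
* Missed-coin handling (closest approach, included in averages) is a
  convention; alternatives change error summaries on poorly flown
  sequences.
* The optional reproduction runner for externally deposited datasets
  requires a user-supplied column/file mapping and has only been
  exercised against synthetic data written in the canonical dialect.
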