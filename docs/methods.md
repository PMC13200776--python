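# Methods

## Grading model

A movement recording is a neutral (rest) landmark frame plus a time-ordered
sequence of frames over a capture window (default 5 s) for one of nine
standardized movement tasks (eyebrow elevation → forehead; eye closure →
eye; cheek inflation, lip pursing, lateral mouth movements right/left, wide
mouth opening, mouth-corner elevation, showing the teeth → mouth). The
diagnostic minimum is the 3-grimace set {eyebrow elevation, eye closure,
show teeth}, one task per region; the full 9-task battery is accepted and
pooled.

**Head-motion removal.** Raw landmark trajectories confound facial movement
with rigid head motion. Before any displacement is measured, each frame is
rigidly aligned to the neutral frame by least-squares (Kabsch) superposition
of the midline landmarks, which are treated as stationary relative to the
skull. At least three non-collinear midline landmarks are required for the
alignment to be determined; with fewer, frames are used as-is.

**Amplitude.** For a region–side landmark set, the amplitude is the mean
over its landmarks of the maximum Euclidean displacement (mm) from the
neutral position across all frames. The per-landmark maximum makes the
statistic insensitive to frame rate and to where in the window the peak
occurs; averaging over landmarks (rather than taking their max or sum) keeps
the value on the scale of a single landmark excursion and damps single-point
tracking errors.

**Symmetry ratio.** r = min(A_affected / A_contralateral, 1), clipped
because the index is defined only up to "normal"; supranormal affected-side
movement is not rewarded. A dead zone (default 0.5 mm, configurable) handles
tasks with no evaluable motion: if both amplitudes fall below it the region
is treated as symmetric (r = 1) — absence of motion is not asymmetry — and
if only the affected amplitude falls below it the region is fully paretic
(r = 0). The ratio is therefore discontinuous at the threshold; the default
sits well below physiological task amplitudes (≈ 4–10 mm) and well above
sensor noise, so the discontinuity is rarely exercised in practice.

**Composite.** DFI = 100 × (0.10 r_forehead + 0.40 r_eye + 0.50 r_mouth).
Regions probed by several tasks use the mean of per-task ratios (mean rather
than min, matching the graded character of the composite). The weights are a
fixed property of the index, not tunable. Output files report the composite
to one decimal; internal computation keeps full precision.

**Affected side.** When not supplied by the user, the affected side is
inferred as the hemiface with the smaller weight-averaged amplitude. An
exact tie is refused with a request for an explicit override (a perfectly
symmetric face has no meaningful affected side), and an override always
wins — clinically the side is known.

## Scale conversion

All four scales are standardized so 100 % = intact function: SI
(10 − SI)·10, HBS (6 − grade)·20, SFGS/DFI identity. These linear forms
reproduce the published anchor (DFI 60 ↔ SI 4 ↔ HBS III ↔ SFGS 60) exactly;
alignments between other intermediate grades are this package's linear
interpolation. Converting to a discrete scale rounds to the nearest grade
with exact ties toward worse function (conservative clinical reporting);
round trips on every legal SI and HBS grade are exact.

## Questionnaires

FDI subscales (5 items each, 1–5) map linearly onto 0–100 %:
percent = (sum − 5) × 5. This transformation is anchored to the published
cohort table: physical item means 4.4 + 4.5 + 4.5 + 4.2 + 4.4 = 22.0 →
85.0 %, matching the printed subscale composite exactly. One missing item is
imputed by the subscale mean of the answered items; more are refused. SUS:
positive items {1,3,5,7,9} contribute response − 1, negative items
{2,4,6,8,10} contribute 5 − response, composite = 2.5 × sum; bands ≥85
excellent, 70–84 good, 50–69 acceptable, <50 poor. Likert summaries use
sample SD (n − 1) throughout, with SD reported as 0 (and n flagged) for a
single respondent.

## Agreement statistics

Spearman ρ uses mid-ranks for ties (scipy); a constant vector is refused
rather than returning NaN. Bland–Altman reports bias, SD of the differences
(n − 1), and limits of agreement at bias ± 1.96 SD (the conventional normal
multiplier, not a t-quantile). Differences are taken instrument − comparator
so positive bias reads as instrument optimism.

ICC comes from the two-way subjects × measurements ANOVA mean squares MSR,
MSC, MSE: consistency-single (MSR−MSE)/(MSR+(k−1)MSE); consistency-average
(MSR−MSE)/MSR (≡ Cronbach α, verified to 1e-9 as a property test);
absolute-single (MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n); absolute-average
(MSR−MSE)/(MSR+(MSC−MSE)/n). Both type axes (absolute agreement and
consistency) are exposed explicitly because the "2-way mixed / absolute
agreement" terminology is used inconsistently across taxonomies; either
reading is reproducible. Significance is the F-test MSR/MSE on
(n−1, (n−1)(k−1)) df; values are always reported with a significance flag
rather than suppressed. Interpretation bins: ICC <0.4 unacceptable, 0.4–0.6
fair, 0.6–0.75 good, ≥0.75 excellent; α <0.7 unacceptable, 0.7–0.8 fair,
0.8–0.9 good, ≥0.9 excellent (boundaries belong to the upper bin). Tables
with zero between-subject variance report ICC 0 with a degenerate flag.

The paired change test gates on Shapiro–Wilk of the paired differences at
α = .05: normal → paired t test, otherwise Wilcoxon matched-pairs
signed-rank; all base tests are scipy's.

## Synthetic data

`simulate_recording` plants per-region severity ratios on a canonical
mirror-symmetric face (3 landmarks per region per side, 4 midline anchors,
millimetre scale). Landmarks of the task's region follow a half-sine
activation over the window, peaking at 8 mm on the healthy side — a
realistic full-effort excursion — and at 8 mm × severity on the affected
side. The half-sine is smooth and peaked, so max-displacement amplitude
extraction recovers the planted peak exactly in the noise-free case (the
default 25-frame grid contains the mid-window peak). Isotropic Gaussian
landmark noise (per frame) models sensor jitter.

`simulate_cohort` emulates a 4-week observational design: baseline true
function ~ Normal(40, 15) % truncated to [0, 100] (an acute, predominantly
moderate-to-severe unilateral palsy population; no cohort distribution is
published, so this default is an explicit modelling choice), exponential
recovery toward 100 % with per-patient rate ~ Gamma(shape 4, mean
0.08/day), which brings median function near normal by day 28; visits at
days 0 and 28. Three blinded raters score each visit on SI, HBS, and SFGS
as discretize(truth + rater bias + noise) via the conversion module; the
instrument contributes three repeated captures truth + optional planted
optimism + Normal(0, 5) noise, clipped to [0, 100]. This
truth-plus-bias-plus-noise rater model is the simplest under which the ICC,
Bland–Altman, and correlation targets have closed forms for
parameter-recovery testing.

What the simulator does *not* model: synkinesis, landmark-tracking dropouts,
non-rigid head deformation, learning/fatigue effects across tasks, and any
dependence of rater noise on severity. Passing recovery tests therefore
shows the pipeline's algebra and estimators are correct under the planted
model, not that the index is clinically valid on real faces.

A note on one noise-free property: rank correlation between a continuous
instrumented score and an 11-level ordinal scale is capped slightly below 1
by quantization ties (≈ 0.98 for the default baseline spread); the
noise-free Spearman consistency check uses the effectively continuous SFGS
for the ≥ 0.99 bound and a 0.97 bound for SI.

## Problem sizes and numerics

Default test problem sizes: 25 frames per recording, 3- or 9-task
batteries, cohorts of 50–200 patients, 100–500 Monte-Carlo replicates —
chosen so every recovery property is estimated with comfortable margin
while the whole suite runs in seconds. Tolerances: geometric identities to
1e-9 mm (Kabsch alignment introduces ~1e-13 rounding); noise-free composite
recovery to 1e-6 percentage points; stochastic recovery bands (±2 points on
the composite mean, ±0.03 on ICC, ±1 on planted bias, slope 0.95–1.05)
follow from the planted variances at the stated sample sizes.

## Known limitations

No synkinesis detection; no SFGS item-level subscores (composites only); no
landmark estimation from images or video (the package starts at landmark
coordinates); supranormal ratios are clipped rather than renormalized; the
conversion chart between non-anchor grades is a linear reconstruction.
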