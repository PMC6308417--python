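# Methods

This note documents the models, numerical choices and limitations behind
`insolegait`. It states nothing the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and event detection

A recording is one foot's vertical GRF sampled at a fixed rate (100 Hz by
default), in Newtons or body-weight (BW) fractions. The pipeline smooths
with a centered 5-sample moving average (edges shrink to the available
samples), then detects contacts:

- **Threshold.** The contact threshold is 5 % of the median supra-zero peak
  force (one peak per contact run). Using the median peak rather than the
  global maximum makes the threshold robust to a single hard step.
- **Runs.** Samples above threshold form candidate contacts; sub-threshold
  dips shorter than 0.1 s inside a contact are bridged, runs shorter than
  0.2 s are discarded as noise, and contacts touching the recording edges
  are dropped.
- **Refinement.** Foot-strike is the last sub-threshold sample before a run
  and toe-off the first after it, each refined within ±3 samples. The
  refinement exploits that force onset is locally quadratic in time, so the
  ratio of consecutive smoothed samples near the contact is scale-free
  (≈ 0.36 one sample inside, ≈ 0.2 just outside): a ratio walk
  (continue outward while the next sample ≥ max(0.3·current, 10 % of
  threshold)) lands on the contact sample exactly on noise-free data,
  independent of stance duration and amplitude. Because one noisy sample can
  stop the walk early, the result is only accepted if it lies on the
  near-zero plateau (within 0.25 × threshold of the window minimum);
  otherwise the latest (foot-strike) / earliest (toe-off) plateau sample is
  used. A plain local-minimum search is ill-posed here: the unloaded swing
  baseline is flat, and identically zero without noise.
- **Resolution.** Events are reported at sample resolution (10 ms at
  100 Hz); no sub-sample interpolation. On noise-free synthetic input,
  detected contacts are grid-exact for physiological stance durations
  (0.6–0.9 s) and within one grid sample over stride times 0.8–1.6 s.
- **Outlier strides.** Stride durations are compared against a centered
  9-stride running median (mirror edge handling, so an outlier in the first
  or last stride cannot hide inside its own padded window). A stride
  deviating by more than 3 scaled MADs (MAD × 1.4826, the σ-consistent
  convention, floored at half a sample) is invalidated together with the
  stride that follows it — turns at the walkway ends distort both the turn
  stride and the recovery step. Nothing is deleted: validity flags and
  reasons are recorded, and the filter is idempotent because its statistics
  are always computed over all strides.

## Kinematic parameters

Stride = foot-strike to next ipsilateral foot-strike; stance = foot-strike
to toe-off; swing = toe-off to next foot-strike (so PST + PSWT = 100 %
exactly). All summary statistics use valid strides only. CV is
100 × sample sd (n−1) / mean, in percent.

- **DST.** Per (left) stride, the bilateral-contact time inside the stride:
  the overlap of the left contact interval with the contralateral contact
  intervals, i.e. the loading-response plus pre-swing double-support pieces.
  Strides without exactly one interior contralateral strike, or with a
  missing/spurious overlap piece (e.g. next to a removed turn), contribute
  no DST value. The reported "DST [s]" is the per-stride *sum* of both
  pieces; a single double-support interval is half of it.
- **Phase.** The reference leg is the one with the larger mean swing time
  (ties break to the left leg, with a warning). For each reference stride
  containing exactly one contralateral strike,
  φᵢ = 360·(t_Sᵢ − t_Lᵢ)/(t_L(i+1) − t_Lᵢ); other strides are skipped and
  counted. φ deviation is the mean absolute departure from 180°, normalized
  to percent of 180 by default so that PCI = CV(φ) + φ deviation adds two
  percentages; the raw-degree value is always emitted as an auxiliary
  column, and the convention is switchable (`phase_deviation` in the
  pipeline config).
- **Cadence.** The dominant periodogram frequency of the mean-removed
  left + right GRF in 0.5–4 Hz. The combined signal oscillates at the step
  rate (two steps per stride), which is the printed magnitude of this
  parameter; at least 30 s of signal is required.
- **Spatial estimates.** Speed = distance/duration; step length =
  distance/steps. Distance comes from the cohort manifest (walkway laps):
  insoles do not measure displacement. The step count is every detected
  foot-strike on both feet — turn steps are real steps over the measured
  distance; validity flags exclude strides from timing statistics only.

## Kinetic parameters

Stance segments are cut from the *unsmoothed* series at the detected
contact samples: the moving average skews each M-shape peak toward its
flatter side by about one sample, which would bias the landmark times.
Segments are divided by body weight (weight[kg] × 9.81 when the input is in
Newtons; identity for BW-fraction input), clipped at zero, and linearly
resampled to 101 points (0–100 % stance, the standard grid). Per cycle:

- HPF = first prominent local maximum in (0, 50] % of stance, TOF = last in
  [50, 100) %, MSF = the minimum between them; HPT/MST/TOT are their grid
  positions in % stance. Peaks need a prominence of at least 0.05 BW so
  sensor noise cannot masquerade as a landmark. Cycles without two distinct
  prominent maxima (flat, monotone, single-bump) are excluded and counted.
- Per-cycle extraction comes first and subject-level means/CVs second,
  because the variability parameters are CVs over cycles; extracting from
  an averaged curve would make them undefined.
- Every usable cycle satisfies 0 < HPT < MST < TOT < 100 and
  MSF < min(HPF, TOF) by construction of the search.

## Group statistics and feature selection

Kruskal–Wallis (tie-corrected, via scipy) per parameter across the three
groups; when the omnibus p < 0.05, Wilcoxon rank-sum post-hocs compare each
group against YC plus PD against AMC. No multiple-testing correction is
applied anywhere. Parameters constant across all subjects are flagged and
left untested.

ReliefF (categorical response) and RReliefF (continuous response) are
implemented from their definitions: range-normalized feature differences,
Manhattan distance on range-normalized features for neighbor search, every
instance used as an anchor, deterministic tie-breaks by instance order.
ReliefF weights misses by the class prior relative to the anchor's class;
RReliefF uses rank-exponential neighbor influence exp(−(rank/σ)²) with
σ = 50, normalized per anchor — a conventional default; the choice matters
little at k = 10 and n ≈ 11–16 per group. k defaults to 10 and truncates
(with a warning) when a class or group is too small. Constant predictors
receive weight 0 and are flagged uninformative.

The coordination responses (DST CV, GA, φ deviation, PCI) are continuous,
so their per-group predictor rankings use RReliefF. The pool is the four
demographics (age, sex, weight, height; sex coded 0/1) plus all 28 + 24
gait parameters, minus the response and its algebraic components (PCI's
pool excludes φ CV and φ deviation, and vice versa); clinical covariates
(UPDRS-III, MMSE, LEDD, disease duration, affected side) join the pool for
the patient group only.

## Classification

The classifier is a linear discriminant with pooled full covariance and
empirical priors: score_c(x) = μ_c'Σ⁻¹x − ½μ_c'Σ⁻¹μ_c + log π_c. With 38
training subjects and up to 56 predictors the pooled covariance is
singular; a ridge of 1e-6 × mean diagonal is added (with a warning). Under
leave-one-out cross-validation each fold z-scores the predictors with
training-fold statistics only; the confusion matrix accumulates over folds.
ACC = trace/total; SEN and SPE are macro one-vs-rest averages of per-class
recall and true-negative rate — a three-class problem has no single
sensitivity, and the macro convention treats the groups symmetrically
despite unequal sizes. Clinical covariates are never classification
predictors, since controls lack them.

## Synthetic cohort generator

The generator is the package's testbed: it produces two-insole recordings
whose every parameter is known.

**Timing model.** The left leg carries the base cycle: foot-strikes
accumulate i.i.d. normal stride draws. Right foot-strikes are placed inside
each left stride at a drawn phase (normal around the profile's offset,
clipped to 20–340°). Each toe-off follows the *contralateral* foot-strike
by a nominal double-support interval plus normal jitter
(`double_support_sd_s`) — physiologically, one foot unloads after the other
has loaded. This parameterization makes phase and double-support
variability independent dials (phase noise moves foot-strikes only), at the
cost that swing-time variability is emergent (dominated by stride-time
noise, roughly twice the reported swing CVs) rather than directly set:
stance + swing = stride leaves only two of the three variabilities free,
and the discriminating parameter here is DST CV. A zero-variance profile
reproduces the nominal durations exactly.

**Stance force.** Each contact renders an M-shaped curve on its exact
sample span: a piecewise half-cosine interpolant through (0,0) → (f₁,HPF)
→ (f₂,MSF) → (f₃,TOF) → (1,0). Each segment is strictly monotone with zero
slope at the knots, so the curve has exactly two maxima and one interior
minimum at the requested stance fractions with the requested magnitudes —
chosen over additive bump mixtures precisely because those invariants hold
by construction. Per-cycle landmark fractions and peak magnitudes are
jittered (sd 0.01 fraction and 5 % respectively, clipped to preserve
ordering and the valley) to produce realistic kinetic CVs; i.i.d. Gaussian
sensor noise (default sd 0.01 BW) is added to the assembled series.

**Turns.** Every 18th stride (a 25 m walkway at ~0.7 m steps) is inflated
by a uniform 1.5–2.5 factor with force scaled by 0.8, and its index is
recorded — the ground truth for the outlier filter.

**Group profiles.** Defaults are centered on the three groups' reported
medians: stride ≈ 1.10–1.14 s, swing ≈ 0.37–0.38 s, stance ≈ 65 % of
stride, landmarks at 26/46/74 % of stance, peaks ≈ 0.93–1.10 BW. The
patient profile carries the bilateral-coordination signature: roughly
doubled double-support jitter (0.021 s vs 0.011/0.014 s), wider phase noise
(4.2° vs 2.8/3.0°), a larger between-subject phase-offset spread (3.5° vs
1.0/1.5°, which is what drives φ deviation when per-subject offsets cancel
in the group mean), and larger swing asymmetry (GA ≈ 2.8 vs 0.9/2.2).
Demographics are sampled from normals centered on the reported group
medians, truncated to plausible ranges; patients get UPDRS-III, MMSE, LEDD,
disease duration and an affected side. Between-subject variation
(multiplicative jitter on tempo, swing ratio, double-support sd, phase sd,
peaks, step length, sized from the reported between-subject sd columns) is
applied per subject; it can be disabled (`subject_variation=False`) for
zero-variance oracle checks. Patient double-support jitter scales with
disease duration (×(1 + 0.12·(years − 4))), so clinical status genuinely
predicts double-support variability in the feature-selection analyses.

**What the generator does not emulate.** Individual pressure-sensor maps
(a coarse grid emitter exists only to exercise the grid-summing reader),
correlated/tempo-drifting stride noise (real gait has long-range
correlations; here stride draws are i.i.d., which inflates emergent swing
CVs), freezing of gait, falls, center-of-pressure or shear forces.
Passing tests therefore demonstrate that the *extraction and inference
machinery* recovers planted structure under realistic noise — not that the
synthetic signals are indistinguishable from real insole data.

## Direction checks on study-scale cohorts

The stochastic acceptance checks generate twenty full-size cohorts
(16/12/11 subjects, 5 min at 100 Hz) and require, in at least 16 of 20
seeds: patient medians above the pooled-control median for DST CV, GA,
φ deviation and PCI; a significant Kruskal–Wallis result for DST CV;
kinematic (dataset I) classification accuracy at least that of kinetics
(dataset II); and a positive RReliefF weight for disease duration in the
patient DST CV ranking. The pooled-control comparison is used uniformly:
the directional claim is patients vs controls, and for GA in particular the
reported between-subject spreads (±2.50 at n = 11) make a per-group median
comparison noise-dominated even under the study's own numbers.

## Problem sizes and runtime

Deterministic recovery checks use 60–250 noise-free strides; Monte-Carlo
checks use 10–20 seeded replicates; the full default pipeline (39 subjects,
5-minute recordings, all four classification datasets) runs in well under
two minutes on one CPU, and the whole test suite in a few minutes.

## Known limitations

- Event times are sample-quantized; at 100 Hz every interval carries up to
  10 ms discretization, visible as ±0.5 % in PST-type quantities.
- The outlier filter's 3-scaled-MAD rule flags genuine ≥3.3 σ strides along
  with turns — by design (they *are* duration outliers), but it means the
  invalidated set equals the injected-turn set only on recordings without
  such strides.
- The reported "DST [s]" sums both double-support pieces of a stride
  (≈ 0.33 s for healthy gait); studies reporting a single bilateral
  interval (≈ 0.17 s) differ by a factor of two. CVs are unaffected.
- Absolute CV levels of stance/swing times depend on the generator's
  i.i.d. timing-noise assumption and sample quantization; group
  *differences* in the coordination parameters are the calibrated,
  reproducible quantities.
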