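# Methods

This note documents the models, algorithms and numerical choices behind
`erpdecode`: what the synthetic cohort generator emulates, exactly how the
decoder and the statistics are computed, and where the design was genuinely
open and a choice had to be made.

## Synthetic ERP cohorts

### Signal model

An epoch is a sum of ERP components, each the outer product of a scalp
topography and a Gaussian temporal kernel
`A · exp(−(t − μ)² / (2σ²))`, hard-truncated to zero beyond `|t − μ| > 4σ`.
The truncation makes the pre-stimulus guarantee exact: any component whose
latency satisfies `μ − 4σ > 0` contributes *nothing* to the −200..0 ms
baseline, so baseline decodability can only come from noise.

Default component set (amplitudes at the peak channel, µV):

| component | latency (ms) | width σ (ms) | amplitude | peak channel |
|-----------|--------------|--------------|-----------|--------------|
| P1        | 100          | 12           | +3        | Oz           |
| N1        | 75           | 12           | −2        | Oz           |
| N2        | 140          | 18           | −3        | Cz           |
| P2        | 230          | 25           | +5        | Fz           |
| P3        | 450          | 80           | +10       | Pz           |

Topographies are Gaussian decays of a schematic 2-D projection of a
30-channel extended 10/20 montage (no forward head model — the decoder only
needs between-channel pattern structure).  The P3 kernel (σ = 80 ms) has
substantial mass over ~350–550 ms, matching where broad target-locked
positivities live in oddball data.

Group/run structure: multiplicative gain rules per (group, component) with
one gain per run.  Defaults encode the study condition the analysis must
recover — placebo-only growth with a larger run1→2 than run2→3 step
(P2: 1.0/1.50/1.65, P3: 1.0/1.30/1.45), study group flat.  These gains are
*calibrated, not measured*: no quantitative per-run effect size exists to
copy, so they were set once so that group-mean decoding at the default
cohort sizes lands where published ERP decoding studies of this design
land (~0.4–0.5 in the P2 window, peak ~0.55–0.6 near 460 ms, chance
baseline), and then frozen.

### Noise model

Four sources, all per-trial:

* **1/f background** (`pink_sd`, default 2.5 µV RMS per channel): spectra
  shaped as amplitude ∝ 1/√f.  Crucially it is *spatially correlated*:
  channels mix through the Cholesky factor of a Gaussian correlation kernel
  over schematic scalp distance (`spatial_scale` = 0.45, unit diagonal so
  every channel keeps exactly `pink_sd` RMS).  Spatial smoothness matters,
  not just amplitude: with independent per-channel noise the 30-dimensional
  feature space contains 30 independent noise directions, and a max-margin
  classifier trained on 6 exemplars happily separates classes along them,
  generalising at chance no matter how strong the signal.  Volume-conducted
  ongoing EEG is smooth across the scalp (effectively low-rank), which is
  precisely what makes tiny-training-set ERP decoding feasible; the
  generator reproduces that property.
* **Alpha oscillation** (`alpha_amp` = 3 µV, 10 Hz): fixed posterior
  topography (Gaussian around POz), random phase per trial, coherent across
  channels within a trial.
* **Sensor noise** (`white_sd` = 2 µV): independent per channel and sample.
* **Trial-to-trial component variability**: multiplicative amplitude jitter
  (SD 0.15) and latency jitter (SD 15 ms) per component per trial — the
  variability that motivates trial-averaged folds in the first place.

All randomness of a subject flows from one generator seeded by
`(subject_seed)`; cohort subject seeds derive from the master seed, so a
cohort is a pure function of its configuration.

### What the generator does *not* emulate

No forward modelling of cortical sources or realistic electrode geometry;
no continuous EEG, eye blinks, muscle artifacts or non-stationary drifts;
no behavioural responses or standard-stimulus trials; no between-subject
variation in component topographies or latencies (between-subject
variability arises only from noise realisations, making synthetic cohorts
somewhat more homogeneous than real ones).  Passing tests therefore show
that the pipeline recovers amplitude-modulation effects embedded in
realistic stationary noise — not that it is robust to every artifact class
of real recordings.

## Preprocessing

Order: baseline correction → peak-to-peak rejection → subsampling → floor.

* **Baseline correction**: per trial and channel, subtract the mean over
  −200..0 ms.
* **Peak-to-peak rejection**: a trial is rejected iff max−min exceeds
  100 µV inside any 200-ms window (50-ms steps) on any channel.  Windows
  start at the epoch start; if the duration minus the window is not a step
  multiple, one final window is anchored at the epoch end so coverage is
  complete.  The log records each trial's worst excursion with its channel
  and window.
* **Subsampling**: every 2nd sample (128 Hz effective, 7.8125 ms ≈ 8 ms
  steps), plain striding with no anti-alias filter — each retained
  timepoint is decoded independently, so between-sample aliasing has no
  pathway into the results, and retained samples keep their original
  values.
* **Common floor**: a subject enters a parameter set's analysis iff every
  run retains at least `n_per_avg × n_folds` trials (30/39/40 for the three
  sets).  Floored trials are re-drawn uniformly inside every decoding
  iteration rather than fixed once, so the 100 iterations average over
  trial-selection as well as fold-assignment variability (the more
  conservative reading of "new random assignment").

## Decoding

For each iteration: per class, draw the floored trials, partition into
`n_folds` groups of `n_per_avg`, average each into an exemplar.  For each
fold (held out once) and each timepoint, train 3 one-vs-all soft-margin
linear SVMs on the (k−1)×3 training exemplars' 30-channel voltages, then
label each held-out exemplar by the argmax of the three decision values;
exact ties break to the lowest class index and are counted in the result.
The test design is balanced (one exemplar per class per fold), so overall
proportion correct equals the mean of the confusion diagonal; both are
stored per timepoint, averaged over folds and iterations.

### SVM solver

The classifier is the L2-regularised squared-hinge linear SVM, C = 1, no
feature scaling (exemplars are trial means in µV; channel scale is
homogeneous), bias as an augmented constant feature of value 100
(`intercept_scaling`).  Two numerical points deserve emphasis:

* **The bias must be effectively unpenalised.**  ERP exemplars sit far from
  the origin (all-positive voltages of tens of µV at component peaks), so a
  unit-scale augmented bias — whose squared norm enters the objective — is
  so expensive that the optimum collapses to a degenerate small-norm
  solution that violates every margin slightly and carries no class
  information.  With `intercept_scaling = 100` the bias penalty is
  (b/100)², numerically negligible, matching the unpenalised-bias behaviour
  of the libsvm-family solvers ERP toolboxes use.
* **The dual is solved exactly, not iteratively.**  Each problem has only
  n = 6–9 samples, so the dual is a strictly convex non-negative QP in n
  variables, solved by a Lawson–Hanson active-set method: a handful of
  batched n×n linear solves per problem, vectorised over all
  (iteration × fold × timepoint) problems of a subject at once (~38 000
  problems in ~1 s).  First-order solvers are not an option here:
  trial-averaged exemplars give the dual a condition number of ~10³–10⁵,
  and coordinate descent (liblinear's algorithm) needs ~10⁵ epochs per
  problem to converge on such data.  The test suite verifies the solver
  against a fully converged `LinearSVC` (coefficients to <1e−6 relative)
  and against a free scipy primal minimisation on ill-conditioned cases.

A one-vs-all geometric caveat documented here because it shapes every
result: when the three class means are nearly collinear (a single component
modulated in amplitude), the middle class is not linearly separable from
the two outer ones, so its own classifier contributes little and overall
accuracy saturates well below 1 even without noise — with run 1 (the most
distant class under the larger run1→2 step) decoded best.  This is a
property of the method, visible in the windowed confusion matrices, not of
the implementation.

Per-subject RNG streams derive from `(decoding seed, subject index)`, so
cohort results are reproducible and independent of execution order.
`decode_subject` accepts a `time_range` restriction; per-timepoint decoding
is independent, so restricted runs equal the corresponding slice of a full
run (asserted in tests).

## Statistics

* **Permutation t-test vs chance** (`n_perm` default 10 000): subtract
  chance (1/3) from each subject's accuracy curve; each permutation flips
  every subject's whole curve's sign jointly (flips shared across
  timepoints, as the max-statistic logic requires); the null distribution
  is the per-permutation maximum t (upper tail, the stated hypothesis being
  "better than chance"; a two-sided option maximises |t|).  Corrected
  p at a timepoint = proportion of null maxima ≥ its observed t, with the
  observed statistic included in the null so p is never exactly 0.  Sign
  flips only change the per-timepoint mean while the mean square is
  invariant, so the permutation t-values are computed from the flipped
  means alone — one matrix product per batch of permutations.
* **Significant intervals**: maximal runs of consecutive significant
  timepoints as [first, last] ms; single-sample intervals are flagged
  "short" (below the ~8 ms effective resolution, not physiologically
  interpretable).
* **Bins**: ten 50-ms bins tiling 200–700 ms, membership
  `start ≤ t < end`.
* **Mixed ANOVA**: observation units are (subject × parameter set) rows —
  2×3 between cells (condition × set) with the 10-level time factor within.
  Treating subject×set rows as independent is the only reading consistent
  with error dfs of 73 (between) and 657 (within) at 31+24+24 units; the
  overlap of set-1 subjects with sets 2–3 is noted, not modelled.  Effects
  are Type II sums of squares from a full factorial OLS; the between-unit
  error stratum is `T·Σ(unit mean − cell mean)²` with df N − cells, the
  within stratum is the remaining residual with df (N − cells)(T − 1).
  Greenhouse–Geisser ε comes from the pooled within-cell covariance of the
  repeated measures; within-effect p-values are F-tested at ε-scaled dfs.
  Partial η² = SS_effect / (SS_effect + SS_error-of-its-stratum).  Factors
  with a single observed level are dropped from the model automatically.
* **Post-hoc per-bin contrast**: pooled-variance two-sample t-test of
  per-unit bin means (placebo vs study), Cohen's d = mean difference /
  pooled SD.  No multiplicity adjustment across bins by default (the
  original software's post-hoc family is unspecified); the full per-bin
  table is always reported so any correction can be applied downstream.

## Pipeline, I/O, reproducibility

Epochs persist one subject per HDF5 file (`/data`, `/times`, `/run_labels`
plus subject/group/srate/channel attributes) with a CSV cohort manifest;
decoding results likewise (`/accuracy`, `/confusion`, config attributes).
Group accuracy matrices, rejection/floor summaries, intervals, bins, ANOVA
and post-hoc tables are CSV.  Every figure (accuracy curves with thickened
significant spans and the dashed 0.33 chance line, windowed confusion
heatmaps with true labels on the x-axis, bin means ± 95 % CI) writes a CSV
twin containing exactly the plotted numbers.  `run_pipeline` records a JSON
manifest with the config snapshot, seed, package version, per-stage
timestamps and SHA-256 of every output; a content hash over the sorted
file hashes identifies the run, and a re-run with the same config and seed
reproduces it byte-for-byte (tested).

## Problem sizes used in the shipped checks

The automated checks run at desk scale, chosen as the smallest sizes at
which the tested property is stable: null-cohort baseline calibration at
10 subjects/group with 100 iterations restricted to the baseline window;
effect recovery at the default 12 subjects/group, full epoch, 100
iterations; family-wise error over 600 simulated null group datasets at
2 000 permutations; the acceptance script decodes the full default cohort
(24 subjects) in about a minute.

## Known limitations

* Amplitude-only modulation makes class geometry nearly collinear, so
  absolute accuracies depend strongly on the one-vs-all combination rule;
  methods that model class order would behave differently.
* The generator's subjects share topographies and noise covariance;
  between-subject variance is smaller than in real cohorts, so group-level
  effect sizes (Cohen's d) run larger than field-typical for the same
  decoding margins.
* The ANOVA treats subject×set rows as independent (see above).
* Statistical calibration of the tmax test assumes the sign-flip null
  (symmetric subject-level deviations from chance), which holds for
  accuracy curves near chance but is approximate far above it.
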