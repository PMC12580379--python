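# Methods

## Scientific setting

`microact` implements a resting-state EEG microstate temporal-dynamics
analysis paired with bilateral wrist-actigraphy arm-movement metrics, the
combination used to characterize brain-network changes and spontaneous arm
movement after middle-cerebral-artery stroke.  Because clinical recordings
of this kind are not publicly deposited, the package ships first-class
synthetic-data generators with full ground truth; every pipeline stage is
validated against planted structure rather than against irreproducible
patient data.

## Microstate model

The working assumption of microstate analysis is that the scalp potential
field passes through brief (tens of ms) quasi-stable topographies drawn
from a small set of template maps.  Concretely, for channel vector v(t):

* **GFP** (global field power) is the spatial population SD across the n
  electrodes at each sample, GFP(t) = sqrt(Σᵢ (vᵢ(t) − v̄(t))² / n).
  GFP peaks mark samples of maximal signal-to-noise; their topographies
  are the clustering input.
* **Modified k-means** is polarity-invariant: a map and its negation are
  the same microstate.  Assignment maximizes squared spatial correlation
  (maps are average-referenced, so spatial correlation equals cosine
  similarity); the centroid update is the first principal component of the
  assigned maps (sign-indeterminate by construction).  The objective and
  model-selection criterion across random restarts is **GEV**, the
  GFP²-weighted fraction of topographic variance explained.  Empty
  clusters are re-seeded from the worst-explained map.
* **Group maps** are obtained by aligning each subject's maps to a
  reference (Hungarian assignment on absolute spatial correlation, with
  polarity flipped to positive correlation) and averaging channel-wise.
* **Canonical labels A–D** are assigned by Hungarian matching to built-in
  idealized topographies constructed as spatial gradients over the
  19-channel 10-20 montage: A right-frontal→left-posterior diagonal,
  B the mirror image, C symmetric anterior–posterior, D fronto-central
  versus peripheral.  Ties resolve to the smallest label index.
* **Back-fitting** labels every sample (not only peaks) with the best map
  by absolute spatial correlation.  No temporal smoothing is applied by
  default; an optional minimum-duration merge absorbs runs shorter than a
  configurable threshold into the better-correlated neighbor.
* **Parameters** per state: coverage (fraction of analyzed samples), mean
  duration (ms), occurrence (runs per second), and the transition matrix.
  Transitions are conditional on leaving a state: P(next = s′ | leave s),
  with the diagonal excluded and rows normalized over runs that have a
  successor within the same epoch.  Epoch-final runs contribute no
  transition.  A state with no outgoing transition gets a NaN row and an
  explicit `transition_defined = False` flag rather than zeros.  Coverage,
  occurrence and duration satisfy coverage = occurrence × duration / 1000
  exactly, since all runs (including edge-truncated ones) enter all three.

Clustering is fit on GFP-peak maps only; parameters are computed over all
samples of the back-fitted segmentation.  Both choices have config
switches where the field is genuinely split (peak-only parameters,
unconditional transition rates).

**Duration under label noise.**  Mean duration is the parameter most
sensitive to samplewise misclassification: at snr 4 (~11 % label errors)
unsmoothed runs fragment to a fraction of the generative dwell, while a
minimum-duration merge over-corrects because a geometric dwell
distribution puts substantial mass (~29 % at a 20 ms floor) on genuinely
short runs that the merge absorbs.  The estimator itself is unbiased —
in the high-snr limit recovered duration matches the generative 60 ms
dwell — and coverage, occurrence and transition probabilities stay
within tolerance at snr 4, but absolute duration values from noisy data
should be compared between groups processed identically, not read as
physical dwell times.

## Preprocessing chain

Order: 50 Hz zero-phase IIR notch (Q = 30) → artifact-removal slot (a
no-op by default; synthetic data contain no ocular/myogenic components,
and users with real recordings can inject a cleaner) → 1–45 Hz zero-phase
Butterworth band-pass (order 4 forward–backward, reflect padding of 3×
filter length) → robust bad-channel detection → exclusion rule → spherical
interpolation → average reference → epoch selection.

Decisions where the procedure was underdetermined:

* **Bad channels**: a channel is bad when the robust z-score of its
  temporal SD across channels (median/MAD, scaled by 1.4826) exceeds 4.
  A raw 4 µV SD cut would flag nearly every channel, so the threshold is
  read on the standardized scale.  The criterion is evaluated after
  filtering by default (`bad_detection="pre_filter"` switches it).
* **Exclusion**: a recording with more than two bad channels is excluded,
  boundary tested explicitly (2 → keep, 3 → exclude).
* **Spherical interpolation** is the Perrin-style spherical spline with
  order m = 4, a truncated 50-term Legendre series, ridge regularization
  1e-5, and a free constant term, solved over the good electrodes on the
  idealized unit sphere.  It is cross-checked in the tests against MNE's
  independent implementation (spatial correlation ≥ 0.95).
* **Epoch selection**: the recording is partitioned into non-overlapping
  candidate windows and the five windows with the lowest total channel
  variance are kept in temporal order — a deterministic stand-in for the
  manual "quiet epoch" selection of clinical practice.

## Synthetic EEG generator

The generator emulates what the analysis assumes, and only that:

* **States** follow a semi-Markov process: geometric dwell times on
  samples (memoryless per sample; mean 60 ms by default) and a
  row-stochastic embedded chain over *distinct* next states (zero
  diagonal, uniform off-diagonal by default).  The long-run occupancy is
  the embedded chain's stationary distribution weighted by mean dwell.
* **Templates** are linear spatial gradients along random 3-D axes over
  the unit-sphere electrode positions — smooth, dipolar-looking maps —
  redrawn until all pairwise absolute correlations are below 0.8.
* **Amplitude**: the channel signal is the active template times a
  zero-mean narrowband Gaussian carrier (8–13 Hz band-passed white noise,
  RMS 1).  This mirrors alpha-dominated resting EEG: GFP peaks twice per
  carrier cycle, the topography's polarity flips with the carrier sign
  (the reason the clustering ignores polarity), and virtually all signal
  power lies inside the 1–45 Hz analysis band, so the filtering chain is
  transparent to the planted structure.  A rectified (always-positive)
  envelope was rejected during design: its sub-1 Hz power carries an
  occupancy-weighted mean topography that the 1 Hz high-pass removes,
  which biases recovered maps.
* **Noise** is Gaussian, spatially smoothed with a Gaussian kernel on
  great-circle inter-electrode distance (width 0.35 rad, giving ~0.2 noise
  correlation between adjacent 10-20 electrodes), average-referenced, and
  scaled so signal RMS / noise RMS equals the requested snr (default 4).
  White noise would make spatial correlations trivially low; very smooth
  noise (≥0.6 rad) concentrates into few spatial patterns that overlap
  the template subspace and drives back-fit accuracy below what the
  snr = 4 study conditions are designed to support.

What the generator does **not** emulate: ocular/myogenic artifacts, 1/f
background spectra, line noise, lesion topography or hemisphere-specific
signal loss, inter-subject template variability beyond the random draw.
Passing tests therefore demonstrate correctness of the algorithms under
the stated generative model, not robustness to real-world artifacts.

## Actigraphy

Metrics over the whole record or a configurable day window (default
06:00–22:00; the clinical day/night boundary is not standardized):

* **ULAR** = Σ affected counts / Σ unaffected counts × 100 %, a ratio of
  totals rather than a mean of per-minute ratios (avoids divide-by-zero
  minutes and matches the aggregate definition).
* **Coordination r** = Pearson correlation of the raw per-minute count
  series (no transform).
* **Moderate-activity minutes** = minutes strictly above 500 counts/min
  ("above" read as strict; the boundary is tested), reported for both
  arms since the clinical definition does not say which arm.

The generator draws the unaffected arm as lognormal per-minute counts
(right-skewed, nonnegative; σ_log = 1) with the location set so a target
fraction of minutes exceeds the moderate threshold.  The affected arm is
a Gaussian-copula copy whose copula parameter is root-found against the
*empirical* Pearson r of the realized series (open-loop inversion leaves
~0.05 sampling SD at 1440 minutes), then globally rescaled to hit the
target ULAR exactly.  Strongly negative inter-arm correlations are not
achievable with lognormal marginals; infeasible targets are clamped with
a warning.  Counts are kept continuous (not integer-rounded) so the
degenerate identities (r = 1, ULAR = 100 %) hold to machine precision.
No circadian amplitude modulation is simulated — day/night tags exist,
but the marginals are stationary; night-window metrics on synthetic data
exercise the code path, not a physiological contrast.

## Statistics

* **Covariate adjustment**: OLS residualization of each outcome on the
  covariates plus intercept, residuals shifted back by the grand mean;
  the group comparison then runs on adjusted values.  An alternative mode
  tests the group coefficient inside the linear model directly.  Cohen's
  d is reported for both adjusted (primary) and raw values.
* **Two-sample t**: pooled (Student) by default — the variant that
  reproduces the reference demographic age comparison — with Welch as an
  option.  Summary-statistic and raw-data forms agree to 1e-12.
* **2×2 chi-square**: Yates continuity correction by default (again the
  variant that reproduces the reference demographic sex comparison); the uncorrected
  statistic is available and oracle-tested.
* **Correlations**: Pearson on raw values; Spearman on mid-ranks with a
  t-approximation p (df = n−2), exact permutation p for n ≤ 9.
* **BH-FDR** (step-up) is applied within the outcome family of one
  subgroup comparison.

### Simulation design choices

* The planted-effect power simulation uses a two-outcome family (one
  planted d = 1.2 effect at n = 17/17, one null) with age/sex
  residualization.  An a-priori power analysis (20k replicates) gives
  expected BH-corrected power 0.84 for this family and 0.79 for a
  three-outcome family; the family size was fixed before running the
  test so the 80 % design target is met in expectation.
* Under the global null, BH's expected FDR equals α exactly, so the
  empirical mean over 10⁴ families is a Binomial(10⁴, 0.05) proportion
  that exceeds 0.05 about half the time.  The null-calibration test
  therefore asserts the empirical FDR ≤ 0.05 + 3·SE (≈ 0.0565), a
  one-sided check that the procedure does not exceed its nominal level.
* The exhaustive permutation oracle at n = 4/4 has resolution 1/35, so
  the pooled-t p is compared to it on average over 20 instances (mean
  |Δp| ≤ 0.05, per-instance cap 0.15) rather than per instance.

## Numerical conventions

* Spatial correlation is computed on average-referenced maps, where it
  coincides with cosine similarity; this fixes the formula used in
  assignment, labeling and GEV.
* GFP uses the population (divide-by-n) convention.
* k-means restarts stop when the GEV gain falls below 1e-7; 50 restarts
  by default.  All stochastic components take explicit seeds and are pure
  functions of them.
* Degenerate quantities (zero unaffected activity, zero variance, states
  without successors) are NaN or raised errors, never silent zeros.
* EDF export quantizes to 16 bits over each channel's observed range
  (~0.005 µV resolution at typical amplitudes); the writer is verified by
  reading files back through MNE.

## Problem sizes

The validation experiments run 10 recovery seeds of five 10-s epochs at
500 Hz (2.5×10⁵ samples, ~4.5×10⁴ state transitions pooled), 10⁴
null families for FDR calibration, and 100 seeded cohorts for the power
simulation; the demo cohort is 10 subjects.  These sizes give Monte-Carlo
error comfortably below each quantity's acceptance tolerance.

## Known limitations

* The microstate pipeline assumes a fixed K = 4; no model-selection
  criteria (CV, Krzanowski–Lai, etc.) are provided.
* No source localization, topographic ANOVA, or between-condition map
  tests.
* The artifact-removal stage is a pass-through slot; real recordings need
  an external cleaner before trusting bad-channel statistics.
* Canonical A–D templates are idealized gradients, adequate for labeling
  clearly dipolar group maps; atypical topographies may need manual
  relabeling.
* Sub-minute actigraphy, nonwear detection and sleep scoring are out of
  scope.
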