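# microact

EEG microstate temporal dynamics and wrist-actigraphy arm-movement
metrics for stroke cohorts — a tested, reusable implementation of the
analysis used to relate resting-state brain-network dynamics, spontaneous
bilateral arm movement, and clinical outcome after middle-cerebral-artery
stroke.

**Who it is for.**  Clinical neurophysiology groups who want the full
chain — EEG cleaning, polarity-invariant microstate segmentation,
temporal-dynamics parameters, actigraphy asymmetry metrics, and the
covariate-adjusted subgroup statistics — as composable, seedable Python
functions rather than a GUI toolbox, plus synthetic-data generators with
planted ground truth so every stage can be validated without patient
recordings.

## The analysis in brief

Resting EEG is modeled as passing through brief quasi-stable scalp
topographies ("microstates", canonically labeled A–D).  For the scalp
vector v(t) over n electrodes:

* global field power `GFP(t) = sqrt( Σᵢ (vᵢ(t) − v̄(t))² / n )`;
* topographies at GFP peaks are clustered with a polarity-invariant
  modified k-means (assignment by squared spatial correlation, centroid
  update by first principal component, objective = GFP²-weighted global
  explained variance, GEV);
* group mean maps are built by Hungarian permutation/polarity alignment,
  labeled A–D against built-in canonical topographies, and back-fitted to
  every sample;
* per state the pipeline reports coverage, mean duration (ms),
  occurrence (1/s), and conditional transition probabilities
  `P(next = s′ | leave s)`.

Wrist actigraphy is summarized per subject as the upper-limb activity
ratio `ULAR = Σ affected / Σ unaffected × 100 %`, the bilateral
coordination index r (Pearson correlation of per-minute counts), and
minutes of moderate activity (> 500 counts/min), each overall and within
day/night windows.  Group and subgroup contrasts use OLS covariate
adjustment, pooled two-sample t-tests, Cohen's d, and Benjamini–Hochberg
FDR; demographic tables use the pooled t and Yates-corrected chi-square.

See `docs/methods.md` for the model assumptions, parameter defaults, and
design decisions.

## Worked example

```python
import numpy as np
from microact import (
    generate_templates, StateSequenceSpec, simulate_state_sequence,
    synthesize_eeg, compute_gfp, find_gfp_peaks, modified_kmeans,
    assign_canonical_labels, backfit, compute_parameters,
    synthesize_actigraphy, SyntheticActigraphySpec,
    compute_ular, compute_coordination_r, t_from_summary, chi_square_2x2,
)

# --- synthetic resting EEG with planted microstate structure ---------
templates = generate_templates(n_channels=19, k=4, seed=1)
spec = StateSequenceSpec(k=4, mean_dwell_ms=60, sampling_rate_hz=500,
                         total_duration_s=50, seed=1)
states = simulate_state_sequence(spec)
eeg = synthesize_eeg(templates, states, 500, snr=4.0, seed=1)

# --- microstate analysis on five 10-s epochs -------------------------
epochs = [eeg.data[:, i*5000:(i+1)*5000] for i in range(5)]
peak_maps = []
for ep in epochs:
    peaks = find_gfp_peaks(compute_gfp(ep))
    peak_maps.append(ep[:, peaks].T)
model = assign_canonical_labels(modified_kmeans(np.vstack(peak_maps), k=4, seed=1))
print(f"GEV = {model.gev:.3f}")

seg = backfit(epochs, model, sampling_rate_hz=500)
params = compute_parameters(seg)
for i, lab in enumerate(model.labels):
    print(f"Ms{lab}: coverage={params.coverage[i]:.3f} "
          f"duration={params.duration_ms[i]:.1f} ms "
          f"occurrence={params.occurrence_per_s[i]:.2f}/s")

# --- actigraphy metrics ----------------------------------------------
acti = synthesize_actigraphy(SyntheticActigraphySpec(
    target_r=0.62, target_ular_pct=30.0, seed=1))
print(f"ULAR = {compute_ular(acti.pair):.1f}%  "
      f"r = {compute_coordination_r(acti.pair):.3f}")

# --- demographic table statistics ------------------------------------
age = t_from_summary(62.44, 9.76, 34, 59.58, 9.15, 50)
chi2, p = chi_square_2x2(21, 13, 25, 25)
print(f"age: t = {age.t_statistic:.3f}, p = {age.p_value:.3f}")
print(f"sex: chi2 = {chi2:.3f}, p = {p:.3f}")
```

Output:

```
GEV = 0.952
MsA: coverage=0.228 duration=9.9 ms occurrence=22.94/s
MsB: coverage=0.231 duration=9.7 ms occurrence=23.88/s
MsC: coverage=0.278 duration=11.9 ms occurrence=23.44/s
MsD: coverage=0.262 duration=13.1 ms occurrence=20.08/s
ULAR = 30.0%  r = 0.620
age: t = 1.369, p = 0.175
sex: chi2 = 0.706, p = 0.401
```

Reading the numbers: the clustering explains 95 % of GFP²-weighted
topographic variance; per-state coverage is near the generative
stationary value of 0.25.  Unsmoothed durations at snr 4 are fragmented
by label noise and are far below the generative 60 ms dwell — see the
duration discussion in `docs/methods.md` before interpreting them.  The
actigraphy generator hits its coordination and asymmetry targets, and
the demographic statistics reproduce their reference values.

## Command-line pipeline

The `microact` console script wires the stages into reproducible runs:

```bash
microact --seed 7 --out run1 simulate      # synthetic cohort + ground truth
microact --seed 7 --out run1 preprocess    # notch, band-pass, bad channels, epochs
microact --seed 7 --out run1 microstates   # per-subject models, group maps, parameters
microact --seed 7 --out run1 actigraphy    # per-subject ULAR / r / moderate minutes
microact --seed 7 --out run1 report        # subgroup comparisons + correlations
microact --seed 7 --out run1 demo          # all of the above
microact --show-config                     # all config keys and defaults
```

Runs are reproducible: identical config and seed give identical outputs.
Subjects failing the bad-channel exclusion rule (more than two bad
channels) are skipped and logged, never silently included.

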