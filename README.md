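# somnentropy

Entropy and linear heart-rate-variability (HRV) analysis of RR-interval
series across sleep stages, with a subject-wise sleep-staging evaluation
harness and a synthetic polysomnography-cohort generator.

Autonomic tone shifts with sleep depth: parasympathetic activity dominates
NREM sleep (heart rate slows, beat-to-beat variability whitens), while REM
restores sympathetically driven, strongly modulated rhythms.  This package
is for sleep and autonomic researchers who want to quantify those shifts
from beat-annotated ECG alone — no EEG — and to ask how much nonlinear
(entropy) descriptors add to classical HRV indices when staging sleep.

## What it computes

Per analysis window (270 s or 300 s, sliding in 30-s steps across a scored
hypnogram, labeled by middle sub-epoch or ≥9-of-10 majority respectively):

* **Six entropy measures** at standard short-term HRV parameters
  (m = 2, τ = 1, r = 0.2σ; B = 64; ξ = 6; m = 3 for PermEn):
  - irregularity: ApEn, SampEn, FuzzyEn, conditional entropy (CE),
    permutation entropy (PermEn)
  - complexity: distribution entropy (DistEn), the normalized Shannon
    entropy of all inter-vector Chebyshev distances
* **17 linear measures**: mRR, SDNN, RMSSD, SDSD, pNN50, pNN30;
  Poincaré SD1, SD2, SD1/SD2, S = π·SD1·SD2; Lomb-Scargle band powers TP,
  VLF, LF, HF, nLF, nHF, LF/HF.

RR series are artifact-cleaned per window (impulse-rejection spike
correction, then removal of intervals outside the global mean ± 3 moving
standard deviations).  The staging harness trains an XGBoost classifier
per task (5-, 4-, 3-class) under subject-wise 8-fold cross-validation with
Bayesian hyperparameter tuning, early stopping, inverse-frequency class
weights, and reports accuracy, Cohen's
κ = (p_o − p_e)/(1 − p_e), and exact TreeSHAP feature importances.

See `docs/methods.md` for conventions, parameter rationale, and known
limitations.

## Worked example

```python
import numpy as np
from somnentropy import (
    CohortSpec, EpochScheme, generate_cohort,
    make_subject_folds, make_task, train_and_predict, TrainConfig,
)
from somnentropy.staging import compute_feature_table

cohort = generate_cohort(CohortSpec(n_subjects=16, seed=7))      # 16 nights
table = compute_feature_table(cohort, EpochScheme(window_len=300))

stage_means = (
    table.groupby(["subject_id", "stage"])["sampen"].mean()
    .groupby("stage").mean()
)
print(stage_means.round(3))

folds = make_subject_folds(table["subject_id"].unique(), k=8, seed=7)
res = train_and_predict(
    table, make_task(3), folds,
    TrainConfig(n_bo_init=4, n_bo_iter=4), seed=7,
)
kappas = [r.kappa for r in res]
print(f"3-class kappa: {np.mean(kappas):.3f} +/- {np.std(kappas, ddof=1):.3f}")
```

Output:

```
stage
N1     1.708
N2     2.062
N3     2.151
REM    1.274
W      1.204
Name: sampen, dtype: float64
3-class kappa: 0.920 +/- 0.118
```

SampEn rises monotonically from wake (1.20) through N1 and N2 to deep
sleep (2.15) — beat-to-beat irregularity grows with NREM depth — and
collapses again in REM (1.27), whose strong low-frequency modulation makes
the rhythm predictable.  The 3-class (W/NREM/REM) staging reaches κ ≈ 0.92
on this synthetic cohort, whose stage-conditional structure is cleaner
than real polysomnography; the value demonstrates the harness, not
clinical performance.

## Command line

```bash
somnentropy simulate --subjects 16 --hours 6 --seed 42 --out data/
somnentropy features --beats 'data/*_beats.csv' --hypnograms 'data/*_hypnogram.csv' \
    --epoch-length 300 --out features.csv
somnentropy stage --features features.csv --task 3 --seed 42 --out results.json
```

## Layout

```
src/somnentropy/
  io.py          # beat/hypnogram/feature-table I/O, stage-label mapping
  preprocess.py  # spike correction + moving-SD outlier removal
  epochs.py      # 270-s / 300-s sliding-window construction and labeling
  entropy.py     # ApEn, SampEn, FuzzyEn, DistEn, CE, PermEn
  hrv_linear.py  # time-domain, Poincaré, and spectral features
  staging.py     # feature table, folds, XGBoost harness, kappa, SHAP
  synthetic.py   # hypnogram + stage-conditioned RR generator, artifacts
  cli.py         # thin command-line wrappers
```
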