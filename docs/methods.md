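# Methods

`somnentropy` quantifies the irregularity and complexity of heart-rate
variability (HRV) across sleep stages and evaluates how much those
quantities contribute to ECG-only sleep staging.  This note documents the
models, parameter choices, numerical conventions, and the limits of what
the synthetic test bed can show.

## Epoch construction

Sleep is scored in 30-s sub-epochs (stages W, N1, N2, N3, REM).  Entropy
estimation needs several minutes of beats, so analysis windows are built by
sliding a long window across the hypnogram in 30-s steps:

* **270-s scheme** — nine sub-epochs per window; the window inherits the
  stage of the *middle* sub-epoch.  Every position yields a label, but a
  window may mix stages.
* **300-s scheme** — ten sub-epochs per window; the window is labeled only
  when at least 9 of 10 sub-epochs agree, otherwise it is discarded.
  Labels are purer; coverage is sparser around stage transitions.

Windows covering unscored/movement-time (EXCLUDED) sub-epochs are dropped
in both schemes, as are windows with fewer than 100 preprocessed RR
intervals (`min_beats`; template-matching entropies at m = 2 are
meaningless on very short series, and the floor also removes windows
emptied by artifact deletion).  RR intervals are assigned to the window
containing their terminating R-peak, with half-open `[t0, t1)` bounds so
overlapping windows never dispute a beat.

## RR preprocessing

Applied per analysis window, in two passes:

1. **Spike correction.**  A beat whose deviation from the median of the
   five surrounding intervals exceeds 4 robust-z units — the scale being
   1.483 x the window's global median absolute deviation — is replaced by
   that local median (impulse-rejection filtering).  The threshold is
   configurable; a deviation rule with no magnitude threshold would flag
   roughly half of all beats, so the robust-z form is used.  A constant
   series has MAD 0; the robust z is then defined as 0 and nothing is
   flagged.
2. **Out-of-band removal.**  Intervals strictly outside the window's
   global mean +/- 3 local standard deviations are deleted, the SD taken
   over a centered 100-beat moving window that shrinks at the series
   edges.  Deleted intervals leave gaps; surviving beats keep their
   original timestamps, so spectral analysis runs on the true uneven
   sample times and no interpolation artifacts are introduced.  Deletion
   (rather than interpolation) is a deliberate choice and a sensitivity
   caveat: interpolation would slightly raise regularity.

## Entropy measures

Six estimators per window, on the preprocessed RR series, at the standard
short-term HRV parameters: m = 2, tau = 1, r = 0.2 sigma for ApEn, SampEn,
FuzzyEn; B = 64 histogram bins for DistEn; xi = 6 quantization levels for
conditional entropy (CE); m = 3 for permutation entropy (PermEn).  sigma is
the *sample* standard deviation (N-1), making the template measures exactly
invariant under affine rescaling of the series.

Conventions that matter numerically:

* Embeddings at dimension m use N - m*tau vectors (and N - (m+1)*tau at
  m+1); PermEn uses the classical N - (m-1)*tau ordinal windows.
* ApEn includes self-matches and counts d <= r; SampEn excludes
  self-matches and counts d < r.  Chebyshev distance throughout.
* FuzzyEn replaces the hard match with the membership
  exp(-ln(2)(d/r)^2), which equals 1/2 exactly at d = r and keeps the
  estimator finite whenever sigma > 0.
* DistEn is the base-2 Shannon entropy of the B-bin histogram of all
  off-diagonal inter-vector distances, normalized by log2(B); bins span
  [min, max] of the observed distances, and an all-equal distance set
  gives 0.
* CE quantizes the series uniformly over its full range (the maximum maps
  to the top level), forms m- and (m+1)-symbol pattern codes, and reports
  SE(z) - SE(w) + perc(m)·SE(1) in nats (natural log; the measure is
  unnormalized), where perc(m) is the fraction of m-patterns seen exactly
  once.
* PermEn ranks each 3-tuple with a stable sort (ties broken by order of
  occurrence) and normalizes by log2(3!) so the value lies in [0, 1].

Degenerate inputs (constant series; no template matches for SampEn) yield
NaN with a named flag instead of an exception; rows are carried into the
feature table and imputed with the training-fold median at model-fit time.

A caveat on ApEn: averaging the logarithm of small match counts biases
ApEn low in a way SampEn's ratio construction avoids.  At N = 4000,
m = 2, r = 0.2 sigma on i.i.d. Gaussian noise the bias is about 0.12
natural-log units below the analytic conditional-match value
-ln(2 Phi(r / sigma sqrt(2)) - 1) ≈ 2.19, while SampEn lands within ~0.01
of it.  This is a property of the estimator, not an implementation error;
the test suite asserts SampEn against the analytic value and ApEn against
its known biased position.

## Linear HRV measures

The 17 standard features: mRR, SDNN, RMSSD, SDSD, pNN50, pNN30 (time
domain); SD1, SD2, SD1/SD2, ellipse area S = pi·SD1·SD2 (Poincaré; SD1 =
SDSD/sqrt(2) algebraically); TP, VLF, LF, HF, nLF, nHF, LF/HF (frequency
domain).  Sample variance is used everywhere, consistent with sigma above.

Spectral powers come from the Lomb-Scargle periodogram evaluated on the
beat timestamps — the natural estimator for an unevenly sampled, possibly
gapped tachogram — scaled one-sided so that a tone of amplitude A
integrates to A^2/2 (band-limited broadband inputs reproduce the signal
variance within a few percent).  The frequency grid spans 1/(2T) to 0.4 Hz
at 2x the natural resolution 1/T; denser grids were checked and change
band powers only in the fourth digit.  Band edges are half-open
(VLF 0.0033-0.04, LF 0.04-0.15, HF 0.15-0.4 Hz); TP integrates
0.0033-0.4 Hz, i.e. power below 0.0033 Hz is excluded.  Normalized powers
follow the Task Force convention nLF = 100·LF/(LF+HF), so nLF + nHF = 100
identically.  A 4-Hz cubic-spline resampling + Welch path is available
behind the same interface for cross-checks.

## Staging evaluation

All 23 features (or 17 in the linear-only ablation) feed a gradient-boosted
decision-tree ensemble (XGBoost, `multi:softprob`) for three tasks:
5-class (W/N1/N2/N3/REM), 4-class (N1+N2 merged into light sleep, N3 as
deep sleep), and 3-class (W/NREM/REM).

Cross-validation is subject-wise: 8 folds, 2 test subjects each, disjoint
and jointly exhaustive; 2 further subjects (deterministically the next
fold's test pair) are held out for validation.  No subject's epochs ever
appear on both sides of a fit.  Class imbalance is handled with
inverse-frequency sample weights computed on the training fold; NaN
features are imputed with training-fold medians.

Hyperparameters (max depth 2-10, learning rate 0.01-0.3 log-uniform,
subsample and column subsample 0.5-1.0, L1/L2 regularization 0-5) are tuned
per fold by Bayesian optimization — a Gaussian-process surrogate (Matern
5/2) with expected-improvement acquisition — against validation-set
Cohen's kappa, the validation metric chosen because kappa corrects for the
heavy stage imbalance.  Boosting stops early after 20 rounds without
validation-kappa improvement.  The tuning budget is configurable
(`TrainConfig.n_bo_init/n_bo_iter`, default 8 + 22 evaluations); the test
suite and acceptance script run reduced budgets (0-8 evaluations), which
trades a little accuracy for runtime and does not affect any directional
comparison.

Performance is reported as accuracy and Cohen's kappa
(kappa = (p_o - p_e)/(1 - p_e), p_e from the confusion-matrix marginals),
mean +/- SD over folds; scheme and ablation contrasts additionally get a
per-fold Wilcoxon signed-rank p-value, reported but never used as a gate.
Feature importances are mean absolute Shapley attributions per feature and
class, computed with the ensemble's exact TreeSHAP.

## Synthetic cohort

The generator is a phenomenological stand-in for polysomnographic
recordings, not a physiological model.  A semi-Markov hypnogram walks
W → N1 → N2 → N3 → N2 → REM (with optional brief awakenings) in
realistic dwell times, N3 shrinking and REM growing across ~90-min cycles;
direct W → N3 jumps cannot occur.  Beats are emitted sequentially: each RR
interval is the stage's mean plus 0.10-Hz and 0.25-Hz sinusoidal
modulations plus AR(1) noise, floored at 0.3 s.

The per-stage defaults encode the autonomic picture the pipeline is meant
to recover: wake and REM have strong, predictable low-frequency modulation
and highly autocorrelated noise (low template entropies); NREM depth trades
modulation amplitude for progressively whiter noise (template entropies
rise W → N1 → N2 → N3) and lower heart rate (mean RR 0.85 s in W up to
1.05 s in N3, 0.90 s in REM).  Deeper NREM additionally carries occasional
enlarged noise innovations (`tail_prob`/`tail_scale`, sigh-like RR
excursions small enough to pass the artifact filters); these concentrate
the inter-vector distance histogram and give N3 the lowest distribution
entropy, mirroring the dissociation between irregularity and complexity
that motivates carrying DistEn alongside the template measures.  Per-stage
constants are fixed in `DEFAULT_STAGE_PARAMS` so calibration tests are
stable; per-subject variability is a multiplicative offset shared across
stages, which preserves within-subject stage orderings.  A
`STRONG_SEPARATION_PARAMS` preset with exaggerated contrasts exists purely
for classifier sanity benchmarks.

Artifact injection adds ground-truth-flagged spikes (isolated ~1.7x
pauses, 2 per 1000 beats) and out-of-band runs (5-beat +/-0.4-0.55-s level
shifts, 3 per 1000 beats, spaced so no analysis window accumulates enough
shifted mass to widen its own acceptance band).  Spikes are sized for the
median filter, runs for the moving-SD band; recovery is scored per
artifact type as sensitivity, and specificity as the fraction of clean
beats left untouched.

What the synthetic bed does **not** emulate: respiratory sinus arrhythmia
coupled to actual breathing, apnea/arousal dynamics, ectopy morphology,
1/f background scaling, and night-to-night nonstationarity.  Passing the
calibration and staging checks therefore demonstrates that the pipeline
measures and discriminates what it claims on data with known structure —
not that any particular accuracy carries over to clinical recordings.

## Problem sizes and runtime choices

The default cohort is 16 subjects x 6 h (mirroring the real database's 16
recordings), used for the stage-profile checks.  The scheme comparison in
the test suite averages 10 independent 6-subject x 2.5-h cohorts, and
classifier sanity checks use an 8-subject x 3-h strongly separated cohort
— sizes chosen so the full suite completes in minutes while leaving the
tested directions unambiguous.  The acceptance script uses the full
16-subject cohort for features and an 8-subject cohort for artifact
recovery.

## Known limitations

* ApEn's finite-sample bias (above) makes its absolute values
  length-dependent; comparisons should hold epoch length fixed, as the
  two schemes do.
* CE's absolute value depends on the quantizer resolution xi; only
  within-parameterization contrasts are meaningful.
* The Lomb periodogram's VLF estimate on 270-300-s windows rests on at
  most one full VLF cycle and should be read as a trend indicator.
* WFDB annotation reading requires the optional `wfdb` package; the CSV
  dialect is the canonical interchange format.
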