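# Methods

`ehgkit` implements an imminent-labor prediction pipeline for women
hospitalized with threatened preterm labor: a 30-min bipolar
electrohysterogram (EHG, abdominal-surface uterine EMG) plus six
obstetric covariates are turned into a binary prediction of delivery
within a 7- or 14-day horizon. Because no public EHG database with
time-to-delivery follow-up exists, the package ships a synthetic cohort
generator that reproduces the statistical structure the analysis needs;
every downstream stage is the real analysis code and runs unchanged on
real recordings supplied as CSV.

## Signal conditioning

Raw monopolar channels (M1, M2, typically 500 Hz) are combined as
`bipolar = M1 - M2` to reject common-mode interference, anti-alias
filtered and polyphase-resampled to 20 Hz, then band-limited to
0.1-4 Hz with a 4th-order zero-phase Butterworth (forward-backward, so
waveform asymmetry is preserved for the time-reversibility feature).
The order of operations matters: decimation happens before the 0.1-4 Hz
band-pass because 4 Hz lies below the 10 Hz Nyquist limit of the target
rate. Recordings already delivered at 20 Hz skip the decimation.

Artifact handling is mask-based, never automatic: a boolean mask (input
file or injected by the generator) marks motion/respiration segments,
and any 120 s analysis window intersecting a masked sample is discarded
whole — artifacted data are excluded, not interpolated. Masks are
decimated conservatively (any masked source sample masks the output
sample). Windows are anchored at sample 0 with 50% overlap (step 60 s);
a mask-free 30-min recording yields 29 windows of 2400 samples.

## Features (23 per recording)

Each feature is computed per window and summarized per recording by the
median over windows, which suppresses overlap redundancy and outlier
windows. Spectral features come from a Welch PSD (Hann, 512-sample
segments, 50% overlap) of the full-band window; the PSD is rescaled so
its integral equals the window variance exactly (Parseval pinned by
construction; all ratio-based features are unaffected). Non-spectral
features are computed after restricting the window to the 0.34-4 Hz
fast-wave-high band, the component tied to myometrial cell excitability.

* **Amplitude/energy** — peak-to-peak amplitude (uV); Teager-Kaiser
  energy, mean of `x[n]^2 - x[n-1] x[n+1]` (amplitude *and* frequency
  sensitive).
* **Spectral** — dominant frequency in 0.2-1 Hz (DF1) and 0.34-1 Hz
  (DF2), PSD argmax with ties broken toward lower frequency; H/L energy
  ratio = energy(0.34-1)/energy(0.2-0.34 Hz); spectral deciles D1-D9 on
  0.2-1 Hz (smallest grid frequency reaching k/10 of in-band energy; D5
  is the median frequency). The decile band is 0.2-1 Hz because the
  spectral mass of interest sits in the two fast-wave components
  (fast wave low 0.2-0.34 Hz, fast wave high above 0.34 Hz).
* **Complexity** — binary and 6-state Lempel-Ziv: equal-probability
  quantization (median split / quantile bins), LZ76 exhaustive-history
  parsing to `c` phrases, normalized `c log_k(N) / N` (tends to 1 for
  i.i.d. symbols); sample entropy `-ln(A/B)` and fuzzy entropy
  (baseline-removed templates, membership `exp(-(d/r)^2)`); spectral
  entropy of the 0.34-4 Hz PSD normalized to [0, 1].
* **Non-linearity / geometry** — time reversibility, the lag-tau
  third moment `mean((x[n] - x[n-tau])^3)` (zero for any linear
  Gaussian process); Poincare SD1/SD2 of the lag-1 return map
  (`SD1^2 = var(diff)/2`, `SD2^2 = 2 var(x) - SD1^2`) and their ratio.

Tunables and defaults (all config-exposed): entropy template length
m = 2; tolerance r = 0.15 of the window SD; fuzzy gradient 2;
reversibility lag tau = 1 sample; Lempel-Ziv alphabet {2, 6}. These
follow the methodological literature for short biomedical records; the
source analysis did not pin them. A window where a feature is undefined
(zero in-band energy, no matching templates, constant signal where a
ratio degenerates) contributes nothing to that feature's median rather
than a filled zero.

The O(N^2) entropy kernels are numba-compiled and enumerate template
pairs through a sort on the first template component; pairs whose
distance bound already exceeds the tolerance (or the distance at which
a fuzzy term drops below exp(-32)) are skipped. The counts are exact
and the fuzzy sums match a direct double loop to well below 1e-9
relative, which the test suite verifies against brute-force references.

## Group comparison

Each of the 29 variables (23 EHG + 6 obstetric) is compared between
classes with the two-sided Wilcoxon rank-sum test: full enumeration of
rank assignments (midranks for ties) when the combined n is at most 20,
otherwise the normal approximation with tie correction. p-values are
reported raw at alpha = 0.05 — the descriptive-table convention this
emulates — with an optional Benjamini-Hochberg column (off by default).
Repeated recordings from the same woman are treated as independent
rows, as the emulated cohort's counts imply.

## Classifier study

Per input set (EHG-only 23, obstetric-only 6, combined 29) and horizon:

1. **SMOTE** balances the minority class to parity (k = 5 neighbors;
   synthetic row = `x_i + u (x_nn - x_i)`, u ~ U(0,1)).
2. **Stratified 1/3-1/3-1/3 split** into train/validation/test.
3. **Standardization + PCA** fitted on training rows only; the smallest
   component count reaching 98% cumulative variance is kept
   (zero-variance features dropped with a warning first).
4. **MLP**: one tanh hidden layer, sigmoid output, full-batch gradient
   backpropagation on cross-entropy with a fixed learning rate (0.5),
   at most 500 epochs, early stopping on validation loss with patience
   20, deterministic per seed. Hidden sizes 2-10 are grid-searched and
   the topology with the best validation AUC is selected (ties: fewer
   units); test rows are never consulted.
5. Thirty random partitions; every metric (accuracy, AUC, F1,
   sensitivity, specificity, PPV, NPV, all percent) is reported as
   mean +/- sample SD per split, with the test ROC averaged vertically
   on a fixed 101-point FPR grid and the test confusion matrix (score
   threshold 0.5) averaged arithmetically. A failed partition is
   logged and skipped; the study requires 25 of 30 to succeed.

**SMOTE ordering.** The default follows the emulated study: balance the
whole dataset, then split. This order leaks information — synthetic
minority rows are interpolations of real rows that may land in other
splits — and measurably inflates validation/test metrics: on a
null cohort (no class signal at all) it yields a mean test AUC near
68% instead of 50%. The `smote_after_split` flag applies SMOTE to the
training third only, which is the leakage-safe variant; the package's
null-calibration checks use it, because with the default order they
would measure the leakage rather than the generator. Results produced
with the default order should be read as optimistic by this mechanism.

## Synthetic cohort generator

Per recording the signal is an additive sum, all at 20 Hz:

* background: Gaussian noise shaped to a 1/f PSD inside 0.1-4 Hz,
  scaled to `background_amp` (default 20 uV SD) — the resting baseline;
* contraction bursts: 45 s Hann envelopes at `burst_rate` (default
  0.4/min) carrying a blend of a pure sinusoid and narrow-band noise at
  `burst_dominant_freq` (default 0.45 Hz); the blend weight
  `regularity` (default 0.35) is the main complexity dial, and burst
  timing jitter shrinks as regularity grows;
* a time-asymmetric component: a fast-rise/slow-decay sawtooth at
  0.35 Hz with quadratic distortion, weighted by `nonlinearity_mix`
  (default 0.15) — the simplest mechanism that injects the positive
  lagged-difference third moment (time irreversibility) without
  touching the linear spectrum much.

The imminent-labor class is drawn with parameters shifted by
`class_effect`: regularity and nonlinearity up, burst amplitude up,
background down, dominant frequency slightly down. At `class_effect=1`
(the default study condition) the group medians reproduce the sign
pattern reported for real cohorts — lower binary/multistate Lempel-Ziv,
spectral/fuzzy entropy and SD1/SD2, higher time reversibility in the
imminent class — and at 0 the classes are identically distributed, an
exact null. Obstetric covariates are drawn per class from truncated
normals whose underlying location/scale are moment-matched numerically
so the *realized* mean/SD equal the emulated cohort's printed values
(naive truncation at 0 would bias the imminent-class cervical length by
about +0.9 mm); `class_effect` interpolates the class moments linearly
from the pooled values. Gestations/parity/abortions are normal draws
rounded to the nearest non-negative integer — their printed SDs exceed
their means, which no truncated normal can reproduce, so rounding is
the closest faithful mechanism and their realized moments are
approximate. Class sizes default to the clinical imbalance: 30/110
(7-day horizon) and 47/93 (14-day).

What the generator does **not** emulate: fetal/maternal ECG and
respiration residues, electrode-contact drift, tocolytic-drug dynamics,
between-woman correlation of repeated recordings, or any physiological
burst micro-structure beyond what the features measure. Passing tests
therefore show that the pipeline recovers class structure *of the kind
the features respond to*, at controlled effect size — not clinical
performance on real EHG.

## Numerical and design notes

* Determinism: one global seed is fanned out per stage via SHA-256 of
  `(seed, stage-name)`; cohorts, SMOTE, splits and MLP training are all
  generator-seeded, so a run is reproducible bit for bit.
* Dominant-frequency ties break toward the lower frequency; deciles are
  non-decreasing by construction; spectral entropy of fewer than two
  positive bins is 0.
* Constant windows: sample/fuzzy entropy 0 (all templates match),
  Lempel-Ziv minimal complexity (c = 1), Poincare descriptors
  undefined (flagged, excluded from the median).
* The exact rank-sum path enumerates up to C(20, 10) ~ 1.8e5
  assignments; beyond that the normal approximation's type-I error at
  alpha = 0.05 is ~0.049 at n = 50 per group (verified by simulation).
* Study problem sizes used in the shipped checks: full-scale cohorts
  (140 x 30 min, 30 partitions) for the null-calibration and
  signal-recovery runs; shorter recordings (6 min) and smaller cohorts
  for structural and smoke tests, where only table shapes and
  determinism are at stake.

## Known limitations

* The balance-then-split default reproduces a leakage-prone evaluation
  design faithfully; absolute metric levels under it are optimistic
  (see SMOTE ordering above).
* Early stopping is driven by the validation loss, so validation-set
  metrics are themselves slightly optimistic; only test-split numbers
  estimate generalization.
* Count covariates' moments are approximate (rounding), and the
  generator's TTD values are uniform within class ranges — adequate for
  labels, not for survival-style analyses.
* EDF input is not supported; recordings are exchanged as CSV
  (`time_s, ehg_uv, artifact_flag`) or with interval mask files.
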