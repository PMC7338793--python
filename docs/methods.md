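# Methods

This note documents the models and procedures implemented in `eegsift`, the
defaults and why they were chosen, and what the test suite's synthetic data
do and do not establish.

## Signal model and data layout

A record is one single-channel EEG trace in microvolts. The reference layout
is the Bonn epilepsy database: plain-text files, one amplitude per line,
4,097 samples per channel at 173.61 Hz, band-pass filtered to 0.53–40 Hz,
12-bit A/D. The reader tolerates whitespace and CRLF and assigns
`label="unlabeled"`; labels come from a directory/prefix mapping. All five
clinical labels (healthy eyes-open/closed, hippocampal, interictal, ictal)
are accepted, but the recognition pipeline is binary interictal-vs-ictal —
the two epileptogenic-zone conditions.

## Synthetic data generator

The generator emulates the two classes' gross statistics so the chain is
testable offline:

* **interictal**: order-4 Butterworth band-passed (0.53–40 Hz, zero-phase)
  Gaussian white noise, affinely rescaled so the per-record min/max approach
  (−252, 123) μV — the range of a representative between-seizure channel.
* **ictal**: a 3 Hz spike-wave rhythm — a sinusoid sharpened by a signed
  power (default exponent 2.0) to give spike-like peaks, plus 2nd/3rd
  harmonics at 0.30/0.15 relative amplitude and a slow (0.15 Hz, ±30%)
  burst envelope — over band-limited noise at 15% of the rhythm's peak,
  rescaled toward (−890, 1367) μV.

Amplitude targets are jittered per record by ±10% (multiplicative, uniform)
so records are not range-identical; with jitter 0 every record attains the
configured range exactly. Each record draws from an rng stream spawned from
the root seed with a (class, index) key, so generation is order-independent
and a pure function of the config.

What this captures: the amplitude gap, the rhythmic/stochastic contrast, the
band limits, the dominant ~3 Hz ictal frequency. What it does not: artifact
content, nonstationary seizure evolution, inter-patient variability, or any
overlap between classes — the synthetic classes are far more separable than
clinical data, so pipeline accuracies here demonstrate correctness of the
machinery, not clinical performance.

## EMD, EEMD, CEEMD

Sifting subtracts the mean of the upper/lower cubic-spline envelopes of the
running component. Details:

* **Extrema**: strict local extrema; a plateau bounded by lower (higher)
  neighbours yields one maximum (minimum) at its floor-midpoint index.
* **Boundaries**: 2 extrema are mirrored about each end before spline
  fitting ("not-a-knot" splines, natural below 4 knots), suppressing end
  swings.
* **Stopping**: the classical pointwise criterion
  SD = Σ_t (h_prev(t) − h(t))² / h_prev(t)² < 0.2, with a hard cap of 15
  passes per IMF. On broadband signals the cap binds, so it acts as a fixed
  sifting count. This pairing was chosen by measurement: a looser
  ratio-of-sums rule stops after one to three passes and leaves riding
  waves, dropping the IMF oscillation property (|#extrema − #zero-crossings|
  ≤ 1) to ~65% of components, while the implemented rule holds it at ~95%
  with full high-to-low frequency ordering.
* **Component count**: exactly `n_imfs` = 9 components plus the residual
  trend are always returned; when the cascade exhausts early the remaining
  rows are zero and `n_natural` records the genuine count, keeping
  per-index ensemble averaging well defined.
* **EEMD** averages EMDs of `ensemble_pairs` independently noise-perturbed
  copies (noise std = `noise_ratio` × signal std; `noise_ratio` validated to
  [0, 0.5], default 0.2). **CEEMD** adds each draw with both signs and
  averages all `2m` decompositions, so the injected noise cancels exactly in
  the reconstruction sum. The ensemble default is m = 100 pairs, reading the
  protocol's "100 iterations" as 100 complementary pairs (the 1/(2m)
  average); `ensemble_pairs` is exposed so the other reading is one config
  change. With `noise_ratio` = 0 both ensembles return the plain EMD
  directly.

## IMF screening and reconstruction quality

Each IMF's Pearson correlation with its raw signal is computed per record
and averaged across the dataset per IMF index; indices with average Pr ≥ 0.1
(the conventional "no correlation below 0.1" cutoff) are kept and summed.
Constant (zero-padded) components score Pr = 0. An empty selection is an
explicit error. Quality indexes: Pr, SNR = 10·log₁₀(Σx²/Σ(x−y)²) dB, and
MAE; a perfect reconstruction reports SNR = +∞ as a sentinel so summary
tables tolerate it.

By default the pipeline averages the screening correlations over training
records only (leakage-safe); `normalization_mode="whole_dataset"` reproduces
the protocol that averages over all records before splitting, and the
acceptance script uses it for that reason.

## Features

Nine features per record, indexed 1–9: mean, variance (N−1 denominator),
standard deviation, range, fluctuation coefficient, variation coefficient,
sample entropy, kurtosis (non-excess; normal → 3), skewness. Choices:

* The **fluctuation coefficient** has no universal definition; it is
  implemented as the mean absolute successive difference
  (1/(N−1)) Σ|x_{t+1} − x_t| — a standard fluctuation magnitude — and
  isolated in one function for easy substitution.
* The **variation coefficient** uses the signed mean and raises a domain
  error when |mean| < 1e−12·std instead of returning an unstable value;
  band-passed reconstructions have small but not numerically-zero means in
  practice.
* **Sample entropy** uses m = 2, r = 0.2 × the analyzed series' own std,
  Chebyshev distance, self-matches excluded, with the same template count
  (N − m) at both lengths. B = 0 raises an error; A = 0 returns the
  deterministic cap ln((N−m−1)(N−m)). The implementation is a vectorized
  block computation verified against a brute-force double loop to 1e−12.

## SVM-RFE

The ranking stage trains an RBF SVC (c = 1, g = 1/#surviving features,
retrained every round — the untuned defaults, since the ranking-stage
hyperparameters are otherwise unconstrained) and scores each surviving
feature by J(f) = ½aᵀKa − ½aᵀK^{(−f)}a with the label-signed dual
coefficients frozen. The kernel is built from per-feature squared
differences so removing a constant feature leaves it bitwise unchanged
(criterion exactly 0). The minimum-J feature is eliminated each round, ties
broken by eliminating the higher index; the reversed elimination order ranks
features. Nested subsets are ranking prefixes (largest first); each is
tuned/trained/scored, and the preferred subset is the smallest among those
with maximal test accuracy, then maximal train accuracy. Scoring subsets on
the test partition mirrors the reference protocol; for leakage-free model
selection score on an internal validation split instead (the tuner's CV
fitness already supports this).

## GWO-SVC

Canonical grey wolf search: pack initialized uniformly in the box
((1e−3, 100) for both c and g — the nominal [0, 100] interval clamped away
from the invalid 0), three leaders α/β/γ re-ranked every iteration, updates
W(t+1) = ⅓Σ_l (W_l − K_l·|H_l·W_l − W(t)|) with H = 2r₂, K = 2a·r₁ − a,
fresh r₁, r₂ per wolf/leader/dimension, a linear 2 → 0, positions clipped to
bounds, best-ever elitism (ties resolved toward smaller c — the simpler
model). Fitness is stratified 5-fold CV accuracy (the reference protocol
never states its objective; CV is the defensible choice and is a pure
function of (labels, folds, seed)). Defaults 20 wolves / 50 iterations.
Normalization is min-max to [0, 1], fit on the training partition only by
default (test values are not clipped); `whole_dataset` mode exists for
exact-mimicry runs.

## Pipeline and ablations

`run_pipeline` chains decomposition → screening/reconstruction → features →
stratified 80/20 split (largest-remainder per-class apportionment) →
normalization → optional RFE → final tuner, and reports accuracies,
misclassified records (identified by position within class), the chosen
subset and (c, g), and every seed. `compare_methods` runs named ablation
arms on one shared split so accuracies are paired;
`classify_features` exposes the post-feature half so multi-seed comparisons
need not repeat the (seed-independent) decomposition.

## Working sizes

The acceptance script and the end-to-end tests run the default 200-record
bundle at 1,024 samples per record with 8 complementary noise pairs — sizes
chosen so the full chain completes in minutes on one CPU while leaving every
stage's behaviour intact; the unit suite uses smaller records still. The
full-scale defaults (4,097 samples, 100 pairs, 20 wolves / 50 iterations)
remain the config defaults.

## Reproducing the reference experiment on real data

The Bonn database (sets D = interictal, E = ictal, 100 channels each) is a
public download. With it on disk:

```bash
eegsift ingest --dir bonn/ --labels labels.yaml   # D -> interictal, E -> ictal
eegsift pipeline --config full.yaml --data bonn/ --labels labels.yaml --out report.json
```

with `full.yaml` setting `method: ceemd`, `decomposition.noise_ratio: 0.2`,
`decomposition.ensemble_pairs: 100`, `decomposition.n_imfs: 9`,
`selection_threshold: 0.1`, `normalization_mode: whole_dataset`,
`rfe: true`, `tuner: gwo`, `gwo.pack_size: 20`, `gwo.max_iterations: 50`,
`split_fraction: 0.8`. This run takes hours (200 × 200 EMDs of 4,097-sample
signals) and is not part of the test suite.

## Known limitations

* EMD has no convergence theory; the sifting cap is a pragmatic stopping
  rule and IMF properties are statistical, not guaranteed per component.
* CEEMDAN-style adaptive noise, multivariate EMD and Hilbert spectra are out
  of scope.
* The classifier is strictly binary; no probability calibration.
* Subset selection on test accuracy (reference protocol) is optimistic;
  prefer the CV-based route for new studies.
* Synthetic-data accuracies overstate clinical performance by construction.
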