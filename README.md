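# eegsift

Seizure EEG recognition by ensemble empirical mode decomposition, iterative
feature reduction, and a swarm-tuned support-vector classifier.

`eegsift` is a library + CLI for discriminating ictal (during-seizure) from
interictal (between-seizure) single-channel EEG. The chain is:

1. **CEEMD** — complementary ensemble empirical mode decomposition. Each of
   *m* Gaussian white-noise draws `N_i` (std = 0.2 × signal std by default) is
   added with both signs; `S + N_i` and `S − N_i` are decomposed by EMD and
   per-index intrinsic mode functions (IMFs) are averaged over all 2*m* runs:
   `C_j = (1/2m) Σ_i (I_{+ij} + I_{−ij})`. The paired noise cancels exactly in
   the reconstruction sum, suppressing mode mixing without the residual noise
   of plain EEMD.
2. **IMF screening and reconstruction** — each IMF's Pearson correlation (Pr)
   with the raw signal is averaged over the dataset; components with average
   Pr ≥ 0.1 are summed into the reconstructed signal. Decomposition quality is
   reported as Pr, SNR (dB) and MAE (μV).
3. **Nine features** per reconstructed record: mean, variance, standard
   deviation, range, fluctuation coefficient (mean absolute successive
   difference), variation coefficient, sample entropy (m = 2, r = 0.2 std),
   kurtosis, skewness.
4. **Kernel SVM-RFE** — backward elimination ranking features by the change
   in the SVC dual cost `J(f) = ½ aᵀK a − ½ aᵀK^{(−f)} a` when feature *f* is
   dropped from the RBF kernel with the dual coefficients frozen; nested
   subsets (ranking prefixes) are each scored and the smallest subset with the
   best held-out accuracy is kept.
5. **GWO-SVC** — an RBF soft-margin SVC whose penalty *c* and kernel width *g*
   are tuned by the grey wolf optimizer (20 wolves, 50 iterations, bounds
   (0, 100]) maximizing stratified cross-validation accuracy, after min-max
   normalization of the features to [0, 1].

Real recordings use the Bonn epilepsy database layout (plain text, one
amplitude per line, 4,097 samples at 173.61 Hz). A synthetic generator
emulates both classes — band-limited noise for interictal records and a
high-amplitude ~3 Hz spike-wave rhythm for ictal records — so the whole
chain runs and is tested fully offline.

## Worked example

```python
import eegsift as es

bundle = es.generate_synthetic_dataset(
    es.SyntheticConfig(n_per_class=20, n_samples=512, seed=7)
)
config = es.PipelineConfig(
    method="ceemd",
    decomposition=es.DecompositionConfig(ensemble_pairs=8),
    gwo=es.GWOConfig(pack_size=10, max_iterations=15, seed=0),
    cv_folds=3,
)
report = es.run_pipeline(bundle, config)
print(f"selected IMFs : {report.selected_imfs}")
print(f"feature order : {report.ranking}")
print(f"chosen subset : {report.chosen_subset}")
print(f"best (c, g)   : ({report.chosen_c:.4f}, {report.chosen_g:.4f})")
print(f"train accuracy: {report.train_accuracy:.4f}")
print(f"test accuracy : {report.test_accuracy:.4f}")
```

prints

```
selected IMFs : [1, 2, 3, 4, 5, 6]
feature order : [4, 7, 3, 5, 2, 8, 6, 1, 9]
chosen subset : [4]
best (c, g)   : (4.0983, 1.6537)
train accuracy: 1.0000
test accuracy : 1.0000
```

Reading: IMF screening kept the six fastest components (the slower ones and
the trend fall below the 0.1 correlation threshold); the ranking puts range
(feature 4), sample entropy (7) and standard deviation (3) first — amplitude
and regularity separate ictal from interictal activity; the smallest subset
with perfect held-out accuracy is `{4}` alone, and the tuned classifier
labels all 8 held-out records correctly. On these well-separated synthetic
classes a single amplitude feature suffices; real EEG needs more of the
ranking.

## Command line

```bash
eegsift synth --n-per-class 100 --seed 0 --out data/         # synthetic bundle
eegsift ingest --dir data/ --labels labels.yaml              # label a directory
eegsift decompose --method ceemd --pairs 100 --in ch.txt --out ch  # IMF CSV
eegsift evaluate --raw ch.txt --imfs ch_imfs.csv --out report.csv  # Pr/SNR/MAE
eegsift features --in data/ --labels labels.yaml --out features.csv
eegsift rank --features features.csv --out ranking.json      # SVM-RFE + subsets
eegsift train --features features.csv --subset 3,4,8 --out model.json
eegsift pipeline --config cfg.yaml --synthetic-seed 0 --out report.json
eegsift compare --configs arms.yaml --out comparison.csv     # ablation arms
```

Config files are YAML with flat dotted keys (`decomposition.ensemble_pairs`,
`gwo.pack_size`, ...); every pipeline report records the resolved config and
all seeds.

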