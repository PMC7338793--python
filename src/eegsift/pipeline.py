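"""End-to-end orchestration: decompose, reconstruct, featurize, select, classify.

The full recognition chain is

    per-record decomposition (EMD / EEMD / CEEMD, or none)
 -> dataset-average correlation screening of IMFs + reconstruction
 -> nine-feature table
 -> stratified train/test split (default 80/20)
 -> [0,1] min-max normalization
 -> optional SVM-RFE ranking, nested-subset evaluation, best-subset choice
 -> final RBF SVC, hyperparameters tuned by GWO (or the untuned default)

Two leakage policies exist for every stage that aggregates across records
(IMF screening, normalization, RFE, tuner fitness): ``train_only`` (the
default; those stages see only training records) and ``whole_dataset``
(exact mimicry of protocols that aggregate over all records before
splitting).  Ablation arms of the comparison harness share one split seed
so their test partitions are identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .classification import (
    GWOConfig,
    SVCHyperparams,
    accuracy,
    default_hyperparams,
    normalize_apply,
    normalize_fit,
    predict_svc,
    train_gwo_svc,
    train_svc,
)
from .decomposition import DecompositionConfig, ceemd, eemd, emd, reconstruct, select_imfs
from .errors import ValidationError
from .feature_extraction import FEATURE_COLUMNS, SampEnConfig, build_feature_table
from .feature_selection import (
    RFEConfig,
    evaluate_subsets,
    make_tuner,
    nested_subsets,
    rank_features,
    select_best_subset,
)
from .signal_io import DatasetBundle

DECOMPOSITION_METHODS = ("none", "emd", "eemd", "ceemd")


@dataclass
class PipelineConfig:
    method: str = "ceemd"
    decomposition: DecompositionConfig = field(default_factory=DecompositionConfig)
    sampen: SampEnConfig = field(default_factory=SampEnConfig)
    rfe: bool = True
    rfe_config: RFEConfig = field(default_factory=RFEConfig)
    tuner: str = "gwo"
    gwo: GWOConfig = field(default_factory=GWOConfig)
    cv_folds: int = 5
    split_fraction: float = 0.8
    split_seed: int = 0
    decomposition_seed: int = 0
    normalization_mode: str = "train_only"
    selection_threshold: float = 0.1

    def __post_init__(self):
        if self.method not in DECOMPOSITION_METHODS:
            raise ValidationError(f"method must be one of {DECOMPOSITION_METHODS}")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValidationError("split_fraction must lie in (0, 1)")
        if self.normalization_mode not in ("train_only", "whole_dataset"):
            raise ValidationError("normalization_mode must be train_only or whole_dataset")
        if self.tuner not in ("gwo", "default"):
            raise ValidationError("tuner must be 'gwo' or 'default'")


@dataclass
class ClassificationReport:
    """Everything one pipeline run produced, with full provenance."""

    train_accuracy: float
    test_accuracy: float
    misclassified_train: list[dict]
    misclassified_test: list[dict]
    chosen_subset: list[int]
    chosen_c: float
    chosen_g: float
    selected_imfs: list[int] | None
    imf_correlations: list[float] | None
    subset_evaluations: list[dict]
    ranking: list[int] | None
    n_train: int
    n_test: int
    config: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def split_dataset(
    bundle: DatasetBundle, fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split; returns (train indices, test indices).

    The total training count is round(fraction * n), apportioned to classes
    by largest remainder so per-class proportions are honored; each class
    must land at least one record in both partitions.
    """
    labels = bundle.labels
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValidationError("both classes must be present to split")
    n = len(bundle)
    n_train_total = int(round(fraction * n))
    quotas = fraction * counts
    base = np.floor(quotas).astype(int)
    remainder = quotas - base
    short = n_train_total - base.sum()
    for idx in np.argsort(-remainder)[: max(short, 0)]:
        base[idx] += 1
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls, quota, total in zip(classes, base, counts):
        if quota < 1 or quota >= total:
            raise ValidationError(
                f"class {cls!r} too small to appear in both partitions"
            )
        members = np.flatnonzero(labels == cls)
        perm = rng.permutation(members)
        train_idx.append(perm[:quota])
        test_idx.append(perm[quota:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _decompose_bundle(bundle: DatasetBundle, config: PipelineConfig):
    """Per-record decomposition with record-split rng streams."""
    method = config.method
    sets = []
    for i, rec in enumerate(bundle):
        if method == "emd":
            sets.append(emd(rec.samples, config.decomposition))
        else:
            ss = np.random.SeedSequence(
                entropy=config.decomposition_seed, spawn_key=(i,)
            )
            fn = eemd if method == "eemd" else ceemd
            sets.append(fn(rec.samples, config.decomposition, np.random.default_rng(ss)))
    return sets


def _misclassified(labels, source_ids, ids, y_true, y_pred) -> list[dict]:
    """Misclassification list identifying records by position within class."""
    out = []
    for i, t, p in zip(ids, y_true, y_pred):
        if t != p:
            within = int(np.sum(labels[: i + 1] == t))
            out.append(
                {
                    "source_id": source_ids[i],
                    "position_in_class": within,
                    "true": str(t),
                    "predicted": str(p),
                }
            )
    return out


def _split_by_labels(labels: np.ndarray, fraction: float, seed: int):
    class _Shim:
        def __init__(self, labels):
            self._labels = labels

        @property
        def labels(self):
            return self._labels

        def __len__(self):
            return self._labels.size

    return split_dataset(_Shim(labels), fraction, seed)


def classify_features(
    x,
    labels,
    config: PipelineConfig,
    source_ids: Sequence[str] | None = None,
) -> ClassificationReport:
    """Split, normalize, optionally RFE-reduce, tune and score a feature table.

    This is the back half of :func:`run_pipeline`, usable directly when the
    feature table was computed once and several split/tuner seeds are to be
    compared without repeating the decomposition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValidationError("two classes required")
    if source_ids is None:
        source_ids = [f"record-{i}" for i in range(len(y))]

    train_ids, test_ids = _split_by_labels(y, config.split_fraction, config.split_seed)
    x_train, y_train = x[train_ids], y[train_ids]
    x_test, y_test = x[test_ids], y[test_ids]
    if config.normalization_mode == "train_only":
        norm = normalize_fit(x_train)
    else:
        norm = normalize_fit(x)
    x_train = normalize_apply(x_train, norm)
    x_test = normalize_apply(x_test, norm)

    tuner = make_tuner(
        config.tuner, gwo_config=config.gwo, folds=config.cv_folds, seed=config.split_seed
    )

    ranking_order = None
    subset_evals: list = []
    if config.rfe:
        ranking = rank_features(x_train, y_train, config.rfe_config)
        ranking_order = ranking.order
        subsets = nested_subsets(ranking)
        subset_evals = evaluate_subsets(subsets, x_train, y_train, x_test, y_test, tuner)
        best_eval = select_best_subset(subset_evals)
        chosen = best_eval.subset
    else:
        chosen = list(range(1, x.shape[1] + 1))

    cols = [f - 1 for f in chosen]
    if config.tuner == "gwo":
        model, params, _ = train_gwo_svc(
            x_train[:, cols], y_train, config.gwo,
            folds=config.cv_folds, seed=config.split_seed,
        )
    else:
        params = default_hyperparams(len(cols))
        model = train_svc(x_train[:, cols], y_train, params)

    pred_train = predict_svc(model, x_train[:, cols])
    pred_test = predict_svc(model, x_test[:, cols])

    return ClassificationReport(
        train_accuracy=float(np.mean(pred_train == y_train)),
        test_accuracy=float(np.mean(pred_test == y_test)),
        misclassified_train=_misclassified(y, source_ids, train_ids, y_train, pred_train),
        misclassified_test=_misclassified(y, source_ids, test_ids, y_test, pred_test),
        chosen_subset=chosen,
        chosen_c=params.c,
        chosen_g=params.g,
        selected_imfs=None,
        imf_correlations=None,
        subset_evaluations=[asdict(e) for e in subset_evals],
        ranking=ranking_order,
        n_train=int(train_ids.size),
        n_test=int(test_ids.size),
        config=asdict(config),
    )


def reconstruct_bundle(
    bundle: DatasetBundle, config: PipelineConfig
) -> tuple[list[np.ndarray] | None, list[int] | None, list[float] | None]:
    """Decompose every record and reconstruct from the screened IMFs.

    Returns (reconstructed series, selected 1-based IMF indices, per-IMF
    average correlations); all None when the method is ``none``.  In
    ``train_only`` mode the correlation averaging for IMF screening uses
    only the training partition of the configured split.
    """
    if config.method == "none":
        return None, None, None
    imfsets = _decompose_bundle(bundle, config)
    raws = [r.samples for r in bundle]
    if config.normalization_mode == "train_only":
        train_ids, _ = split_dataset(bundle, config.split_fraction, config.split_seed)
        sel_sets = [imfsets[i] for i in train_ids]
        sel_raws = [raws[i] for i in train_ids]
    else:
        sel_sets, sel_raws = imfsets, raws
    selection = select_imfs(sel_sets, sel_raws, config.selection_threshold)
    reconstructed = [reconstruct(s, selection) for s in imfsets]
    return reconstructed, selection.selected_indices, selection.correlations.tolist()


def run_pipeline(bundle: DatasetBundle, config: PipelineConfig) -> ClassificationReport:
    """Run the full recognition chain on a labeled two-class bundle."""
    labels = bundle.labels
    if np.unique(labels).size != 2:
        raise ValidationError("pipeline requires a two-class bundle")

    reconstructed, selected, correlations = reconstruct_bundle(bundle, config)
    table = build_feature_table(bundle, reconstructed, config.sampen)
    x = table[list(FEATURE_COLUMNS)].to_numpy()
    report = classify_features(
        x, labels, config, source_ids=[r.source_id for r in bundle]
    )
    report.selected_imfs = selected
    report.imf_correlations = correlations
    return report


def compare_methods(
    bundle: DatasetBundle, configs: dict[str, PipelineConfig]
) -> dict[str, ClassificationReport]:
    """Run several named pipeline arms with one shared split seed.

    All arms are forced onto the first config's split seed and fraction so
    their test partitions coincide and accuracies are paired.
    """
    if len(configs) < 2:
        raise ValidationError("need at least two configs to compare")
    items = list(configs.items())
    ref = items[0][1]
    reports = {}
    for name, cfg in items:
        if (cfg.split_seed, cfg.split_fraction) != (ref.split_seed, ref.split_fraction):
            raise ValidationError(f"arm {name!r} does not share the reference split")
        reports[name] = run_pipeline(bundle, cfg)
    return reports
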