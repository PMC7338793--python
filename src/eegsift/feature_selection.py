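"""Kernel SVM recursive feature elimination (SVM-RFE).

Features are ranked backwards: train an RBF SVC on the surviving features,
score each surviving feature f by the change in the dual cost when f is
dropped from the kernel while the dual coefficients stay frozen,

    J(f) = 1/2 * a^T K a  -  1/2 * a^T K^(-f) a,

where a are the label-signed dual coefficients of the support vectors,
K the RBF kernel on the surviving features and K^(-f) the kernel with
feature f removed; then eliminate the feature with the smallest J and
repeat.  A feature that is constant across the support vectors leaves every
pairwise squared distance unchanged, so its criterion is exactly zero.

The elimination order, reversed, ranks features most-important-first.  The
nested candidate subsets are the prefixes of that ranking; each is scored
by a (tunable) classifier's train/test accuracy and the preferred subset is
the smallest one among those with the best test accuracy (then best train
accuracy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .classification import (
    GWOConfig,
    SVCHyperparams,
    SVCModel,
    accuracy,
    default_hyperparams,
    train_gwo_svc,
    train_svc,
)
from .errors import ValidationError


@dataclass
class RFEConfig:
    """Ranking-stage classifier settings.

    ranking_gamma = None means the default 1/n_surviving_features,
    recomputed each elimination round.
    """

    ranking_penalty: float = 1.0
    ranking_gamma: float | None = None
    min_features: int = 1

    def __post_init__(self):
        if not self.ranking_penalty > 0:
            raise ValidationError("ranking_penalty must be positive")
        if self.ranking_gamma is not None and not self.ranking_gamma > 0:
            raise ValidationError("ranking_gamma must be positive")
        if self.min_features < 1:
            raise ValidationError("min_features must be >= 1")


@dataclass
class FeatureRanking:
    """Elimination-reverse feature order (1-based, most important first)."""

    order: list[int]
    criterion_trace: list[dict[int, float]]

    def __post_init__(self):
        if sorted(self.order) != list(range(1, len(self.order) + 1)):
            raise ValidationError("order must be a permutation of 1..n_features")


@dataclass
class SubsetEvaluation:
    subset: list[int]
    best_c: float
    best_g: float
    train_accuracy: float
    test_accuracy: float

    def __post_init__(self):
        for a in (self.train_accuracy, self.test_accuracy):
            if not 0.0 <= a <= 1.0:
                raise ValidationError("accuracies must lie in [0, 1]")


def rfe_criterion(
    model: SVCModel, surviving: Sequence[int], feature: int
) -> float:
    """J(f) for one surviving feature of a trained ranking-stage SVC.

    ``surviving`` are the 1-based original feature indices the model was
    trained on (columns of its support vectors, in order); ``feature`` must
    be one of them.
    """
    if feature not in surviving:
        raise ValidationError(f"feature {feature} is not in the surviving set")
    sv = model.support_vectors
    a = model.dual_coef
    g = model.hyperparams.g
    col = list(surviving).index(feature)
    # build squared distances feature-by-feature so that removing a constant
    # feature leaves the kernel bitwise unchanged (criterion exactly 0)
    sq = (sv[:, None, :] - sv[None, :, :]) ** 2
    d2_full = sq.sum(axis=-1)
    d2_minus = d2_full - sq[:, :, col]
    k_full = np.exp(-g * d2_full)
    k_minus = np.exp(-g * d2_minus)
    return 0.5 * float(a @ k_full @ a) - 0.5 * float(a @ k_minus @ a)


def rank_features(
    table, labels, config: RFEConfig | None = None
) -> FeatureRanking:
    """Backward elimination ranking of all features.

    Each round retrains the ranking SVC on the surviving columns, scores
    every surviving feature with :func:`rfe_criterion`, and eliminates the
    minimum (ties broken by eliminating the higher feature index).  Rounds
    continue until ``min_features`` remain; any survivors are then ordered
    by their last-round criterion, descending.
    """
    config = config or RFEConfig()
    table = np.asarray(table, dtype=float)
    labels = np.asarray(labels)
    if table.ndim != 2 or table.shape[1] < 1:
        raise ValidationError("table must be 2-D with at least one feature")
    if np.unique(labels).size != 2:
        raise ValidationError("exactly two classes required for ranking")

    surviving = list(range(1, table.shape[1] + 1))
    eliminated: list[int] = []
    trace: list[dict[int, float]] = []
    while len(surviving) > config.min_features:
        gamma = config.ranking_gamma or 1.0 / len(surviving)
        params = SVCHyperparams(c=config.ranking_penalty, g=gamma)
        cols = [f - 1 for f in surviving]
        model = train_svc(table[:, cols], labels, params)
        crit = {f: rfe_criterion(model, surviving, f) for f in surviving}
        trace.append(crit)
        worst = min(surviving, key=lambda f: (crit[f], -f))
        surviving.remove(worst)
        eliminated.append(worst)

    if len(surviving) > 1:
        gamma = config.ranking_gamma or 1.0 / len(surviving)
        params = SVCHyperparams(c=config.ranking_penalty, g=gamma)
        cols = [f - 1 for f in surviving]
        model = train_svc(table[:, cols], labels, params)
        crit = {f: rfe_criterion(model, surviving, f) for f in surviving}
        trace.append(crit)
        surviving = sorted(surviving, key=lambda f: (-crit[f], f))
    order = list(surviving) + eliminated[::-1]
    return FeatureRanking(order=order, criterion_trace=trace)


def nested_subsets(ranking: FeatureRanking) -> list[list[int]]:
    """Prefixes of the ranking, largest first: sizes n, n-1, ..., 1."""
    n = len(ranking.order)
    return [ranking.order[:k] for k in range(n, 0, -1)]


def _gwo_tuner(gwo_config: GWOConfig, folds: int, seed: int):
    def tune(x_train, y_train):
        _, best, _ = train_gwo_svc(x_train, y_train, gwo_config, folds=folds, seed=seed)
        return best

    return tune


def _default_tuner(x_train, y_train) -> SVCHyperparams:
    return default_hyperparams(np.asarray(x_train).shape[1])


def make_tuner(
    name: str = "gwo",
    gwo_config: GWOConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> Callable:
    """A tuner callable (X, y) -> SVCHyperparams, by name: 'gwo' or 'default'."""
    if name == "gwo":
        return _gwo_tuner(gwo_config or GWOConfig(), folds, seed)
    if name == "default":
        return _default_tuner
    raise ValidationError(f"unknown tuner {name!r}")


def evaluate_subsets(
    subsets: Sequence[Sequence[int]],
    x_train,
    y_train,
    x_test,
    y_test,
    tuner: Callable | None = None,
) -> list[SubsetEvaluation]:
    """Tune, train and score a classifier on each candidate subset.

    ``tuner`` maps (X, y) to hyperparameters; default is the untuned
    baseline.  Column restriction uses the subset's 1-based indices.
    """
    tuner = tuner or _default_tuner
    x_train = np.asarray(x_train, dtype=float)
    x_test = np.asarray(x_test, dtype=float)
    out = []
    for subset in subsets:
        cols = [f - 1 for f in subset]
        if min(subset) < 1 or max(subset) > x_train.shape[1]:
            raise ValidationError(f"subset {subset} has out-of-range features")
        try:
            params = tuner(x_train[:, cols], y_train)
            model = train_svc(x_train[:, cols], y_train, params)
        except Exception as exc:
            raise type(exc)(f"subset {list(subset)}: {exc}") from exc
        out.append(
            SubsetEvaluation(
                subset=list(subset),
                best_c=params.c,
                best_g=params.g,
                train_accuracy=accuracy(model, x_train[:, cols], y_train),
                test_accuracy=accuracy(model, x_test[:, cols], y_test),
            )
        )
    return out


def select_best_subset(evaluations: Sequence[SubsetEvaluation]) -> SubsetEvaluation:
    """Smallest subset among those with maximal test then train accuracy."""
    if not evaluations:
        raise ValidationError("no evaluations to select from")
    return min(
        evaluations,
        key=lambda e: (-e.test_accuracy, -e.train_accuracy, len(e.subset)),
    )
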