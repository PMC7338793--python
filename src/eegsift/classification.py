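"""RBF support-vector classification with grey-wolf hyperparameter search.

The classifier is a binary soft-margin SVC with Gaussian RBF kernel
K(u, v) = exp(-g * ||u - v||^2); its penalty c and kernel width g are tuned
by the grey wolf optimizer (GWO), a population search in which every wolf
moves toward the three best solutions (alpha, beta, gamma):

    Q_l = | W(t) - H_l * W_l |          H_l = 2 * r2
    W'_l = W_l - K_l * Q_l              K_l = 2*a*r1 - a
    W(t+1) = (W'_alpha + W'_beta + W'_gamma) / 3

with r1, r2 ~ U(0,1) drawn fresh per wolf, per leader, per dimension, and
the exploration coefficient a shrinking linearly from 2 to 0 over the
iterations.  The fitness maximized here is stratified k-fold
cross-validation accuracy on the training table.

Features are min-max normalized to [0, 1] with parameters fit on the
training partition only (test values may fall outside [0, 1]; they are not
clipped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .errors import OptimizerError, ValidationError


@dataclass
class NormalizationParams:
    """Per-feature min/max observed on the fitting table."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self):
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if np.any(self.maximum < self.minimum):
            raise ValidationError("max must be >= min per feature")

    @property
    def constant_mask(self) -> np.ndarray:
        return self.maximum == self.minimum


@dataclass
class SVCHyperparams:
    c: float
    g: float

    def __post_init__(self):
        if not (self.c > 0 and self.g > 0):
            raise ValidationError("c and g must be positive")


@dataclass
class SVCModel:
    """A trained RBF SVC together with its hyperparameters."""

    estimator: SVC
    hyperparams: SVCHyperparams
    n_features: int

    @property
    def support_vectors(self) -> np.ndarray:
        return self.estimator.support_vectors_

    @property
    def dual_coef(self) -> np.ndarray:
        """Label-signed dual coefficients (y_i * alpha_i) of the support vectors."""
        return self.estimator.dual_coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self.estimator.intercept_[0])

    def decision_values(self, table) -> np.ndarray:
        return self.estimator.decision_function(np.asarray(table, dtype=float))


@dataclass
class GWOConfig:
    """Wolf-pack settings; bounds default to the (c, g) search box.

    The nominal search interval [0, 100] contains 0, which is invalid for
    both c and g, so the lower bound is clamped to 1e-3.
    """

    pack_size: int = 20
    max_iterations: int = 50
    bounds: tuple[tuple[float, float], ...] = ((1e-3, 100.0), (1e-3, 100.0))
    seed: int = 0

    def __post_init__(self):
        if self.pack_size < 3:
            raise ValidationError("pack_size must be >= 3 (alpha, beta, gamma)")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValidationError("each bound must satisfy low < high")


@dataclass
class GWOResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness per iteration (non-decreasing)


def normalize_fit(table) -> NormalizationParams:
    """Per-feature min/max of the fitting table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1:
        raise ValidationError("table must be 2-D with at least one row")
    return NormalizationParams(minimum=table.min(axis=0), maximum=table.max(axis=0))


def normalize_apply(table, params: NormalizationParams) -> np.ndarray:
    """(x - min) / (max - min) per feature; constant features map to 0.

    Values outside the fitted range map outside [0, 1] and are deliberately
    not clipped.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != params.minimum.size:
        raise ValidationError("column count does not match normalization params")
    span = params.maximum - params.minimum
    safe = np.where(params.constant_mask, 1.0, span)
    out = (table - params.minimum) / safe
    out[:, params.constant_mask] = 0.0
    return out


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size != 2:
        raise ValidationError("exactly two classes required")


def train_svc(table, labels, params: SVCHyperparams) -> SVCModel:
    """Fit a soft-margin RBF SVC; deterministic for fixed inputs."""
    table = np.asarray(table, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    est = SVC(C=params.c, kernel="rbf", gamma=params.g)
    est.fit(table, labels)
    return SVCModel(estimator=est, hyperparams=params, n_features=table.shape[1])


def predict_svc(model: SVCModel, table) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != model.n_features:
        raise ValidationError(
            f"expected {model.n_features} features, got {table.shape[1] if table.ndim == 2 else 'non-2D'}"
        )
    return model.estimator.predict(table)


def accuracy(model: SVCModel, table, labels) -> float:
    return float(np.mean(predict_svc(model, table) == np.asarray(labels)))


def cv_fitness(
    params: SVCHyperparams, table, labels, folds: int = 5, seed: int = 0
) -> float:
    """Mean stratified k-fold validation accuracy of an SVC at (c, g).

    Fold assignment is a pure function of (labels, folds, seed).
    """
    table = np.asarray(table, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < folds:
        raise ValidationError("each class needs at least `folds` members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    est = SVC(C=params.c, kernel="rbf", gamma=params.g)
    scores = cross_val_score(est, table, labels, cv=skf, scoring="accuracy")
    return float(scores.mean())


def gwo_optimize(
    objective: Callable[[np.ndarray], float], config: GWOConfig
) -> GWOResult:
    """Maximize ``objective`` over the bounded box by the grey wolf search.

    The pack initializes uniformly inside the bounds; every iteration the
    three fittest wolves lead the update, positions are clipped back into
    the box, and the best-ever position is tracked (fitness ties resolved
    toward the smaller first coordinate, i.e. the smaller penalty c).
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in config.bounds])
    hi = np.array([b[1] for b in config.bounds])
    dim = lo.size
    wolves = rng.uniform(lo, hi, size=(config.pack_size, dim))

    best_pos: np.ndarray | None = None
    best_fit = -np.inf
    history = []

    def evaluate(pos: np.ndarray) -> float:
        val = float(objective(pos))
        if not np.isfinite(val):
            raise OptimizerError(f"objective returned {val} at position {pos}")
        return val

    for it in range(config.max_iterations):
        fitness = np.array([evaluate(w) for w in wolves])
        order = np.argsort(-fitness)
        for k in order:
            f, p = fitness[k], wolves[k]
            if f > best_fit or (f == best_fit and best_pos is not None and p[0] < best_pos[0]):
                best_fit, best_pos = f, p.copy()
        history.append(best_fit)
        a = 2.0 * (1.0 - it / config.max_iterations)
        leaders = wolves[order[:3]]
        new = np.empty_like(wolves)
        for w in range(config.pack_size):
            moves = np.empty((3, dim))
            for l in range(3):
                r1 = rng.random(dim)
                r2 = rng.random(dim)
                h = 2.0 * r2
                k_coef = 2.0 * a * r1 - a
                q = np.abs(h * leaders[l] - wolves[w])
                moves[l] = leaders[l] - k_coef * q
            new[w] = moves.mean(axis=0)
        wolves = np.clip(new, lo, hi)

    return GWOResult(
        best_position=best_pos, best_fitness=best_fit, history=np.array(history)
    )


def default_hyperparams(n_features: int) -> SVCHyperparams:
    """The untuned baseline: c = 1, g = 1/n_features."""
    return SVCHyperparams(c=1.0, g=1.0 / n_features)


def train_gwo_svc(
    table,
    labels,
    gwo_config: GWOConfig | None = None,
    folds: int = 5,
    seed: int = 0,
) -> tuple[SVCModel, SVCHyperparams, GWOResult]:
    """Tune (c, g) by GWO with CV accuracy as fitness, then refit on all rows."""
    gwo_config = gwo_config or GWOConfig()
    table = np.asarray(table, dtype=float)
    labels = np.asarray(labels)

    def objective(pos: np.ndarray) -> float:
        params = SVCHyperparams(c=float(pos[0]), g=float(pos[1]))
        return cv_fitness(params, table, labels, folds=folds, seed=seed)

    result = gwo_optimize(objective, gwo_config)
    best = SVCHyperparams(c=float(result.best_position[0]), g=float(result.best_position[1]))
    model = train_svc(table, labels, best)
    return model, best, result
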