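"""The nine per-record features feeding the seizure classifier.

Canonical index mapping (used verbatim by the ranking stage):

    1 mean (uV)                     6 variation_coefficient (-)
    2 variance (uV^2)               7 sample_entropy (nats)
    3 standard_deviation (uV)       8 kurtosis (-)
    4 range (uV)                    9 skewness (-)
    5 fluctuation_coefficient (uV)

Conventions: variance and standard deviation use the N-1 denominator;
kurtosis is the non-excess standardized fourth moment (a normal series
gives 3); the fluctuation coefficient is the mean absolute successive
difference, (1/(N-1)) * sum |x_{t+1} - x_t|, isolated in one function so an
alternative definition can be swapped in; the variation coefficient is
standard_deviation / mean with the signed mean, raising a domain error when
the mean is numerically zero rather than returning an unstable value.

Sample entropy follows the template-matching estimator: with tolerance
r = r_factor * std(x) and embedding dimension m, B counts pairs (i != j) of
length-m templates within Chebyshev distance r, A the same at length m+1,
both over the first N-m template start points; SampEn = -ln(A/B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FeatureDomainError, InsufficientMatches, ValidationError
from .signal_io import DatasetBundle

FEATURE_NAMES = (
    "mean",
    "variance",
    "standard_deviation",
    "range",
    "fluctuation_coefficient",
    "variation_coefficient",
    "sample_entropy",
    "kurtosis",
    "skewness",
)
FEATURE_COLUMNS = tuple(f"f{i}_{name}" for i, name in enumerate(FEATURE_NAMES, start=1))


@dataclass
class SampEnConfig:
    """Sample-entropy settings: embedding dimension m and tolerance factor."""

    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self):
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if not self.r_factor > 0:
            raise ValidationError("r_factor must be positive")


@dataclass
class FeatureVector:
    """The nine named features of one record, indexable 1-9."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (9,):
            raise ValidationError("FeatureVector holds exactly 9 values")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("features must be finite")

    def __getitem__(self, index: int) -> float:
        if not 1 <= index <= 9:
            raise ValidationError("feature index is 1-based, 1..9")
        return float(self.values[index - 1])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_COLUMNS, self.values))


def sample_entropy(x, config: SampEnConfig | None = None) -> float:
    """SampEn(m, r_factor*std) of a 1-D series.

    Self-matches are excluded.  B = 0 raises InsufficientMatches; A = 0
    with B > 0 returns the deterministic cap ln((N-m-1)*(N-m)), the largest
    finite estimate for the template count.  A constant series (std = 0, so
    r = 0 but all distances are 0 <= r) returns exactly 0.
    """
    config = config or SampEnConfig()
    x = np.asarray(x, dtype=float)
    n = x.size
    m = config.m
    if n <= m + 1:
        raise ValidationError("series length must exceed m + 1")
    r = config.r_factor * float(np.std(x))
    n_templates = n - m  # same template count for lengths m and m+1

    # pairwise Chebyshev distances, built per embedding lag in row blocks so
    # memory stays O(block * N) even for long records
    block = 2048

    def match_counts(length: int) -> int:
        total = 0
        for start in range(0, n_templates, block):
            stop = min(start + block, n_templates)
            d = np.zeros((stop - start, n_templates))
            for k in range(length):
                lag = x[k : k + n_templates]
                np.maximum(d, np.abs(lag[start:stop, None] - lag[None, :]), out=d)
            total += int((d <= r).sum())
        return total - n_templates  # exclude self-matches

    b = match_counts(m)
    if b == 0:
        raise InsufficientMatches("no length-m template pairs within tolerance")
    a = match_counts(m + 1)
    if a == 0:
        return math.log((n - m - 1) * (n - m))
    return -math.log(a / b)


def fluctuation_coefficient(x) -> float:
    """Mean absolute successive difference, (1/(N-1)) * sum |x_{t+1}-x_t|."""
    x = np.asarray(x, dtype=float)
    return float(np.sum(np.abs(np.diff(x))) / (x.size - 1))


def extract_features(
    x, config: SampEnConfig | None = None, record_id: str | None = None
) -> FeatureVector:
    """Compute the nine-feature vector of one series."""
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValidationError("need at least 8 samples for feature extraction")
    mean = float(np.mean(x))
    variance = float(np.var(x, ddof=1))
    std = math.sqrt(variance)
    rng_ = float(np.max(x) - np.min(x))
    fluct = fluctuation_coefficient(x)
    if abs(mean) < 1e-12 * std:
        raise FeatureDomainError(
            "variation coefficient undefined: mean is numerically zero",
            feature="variation_coefficient",
            record_id=record_id,
        )
    variation = std / mean
    sampen = sample_entropy(x, config)
    kurt = float(stats.kurtosis(x, fisher=False))
    skew = float(stats.skew(x))
    return FeatureVector(
        values=np.array([mean, variance, std, rng_, fluct, variation, sampen, kurt, skew])
    )


def build_feature_table(
    bundle: DatasetBundle,
    reconstructed: list[np.ndarray] | None = None,
    config: SampEnConfig | None = None,
) -> pd.DataFrame:
    """One feature row per record, in bundle order, with a ``label`` column.

    ``reconstructed`` supplies the per-record series to featurize (aligned
    with the bundle); None means features are computed on the raw samples.
    Per-record feature errors are re-raised with the record identifier.
    """
    if reconstructed is not None and len(reconstructed) != len(bundle):
        raise ValidationError("reconstructed series must align with the bundle")
    rows = []
    for i, rec in enumerate(bundle):
        series = rec.samples if reconstructed is None else reconstructed[i]
        rid = rec.source_id or f"record-{i}"
        try:
            fv = extract_features(series, config, record_id=rid)
        except (FeatureDomainError, InsufficientMatches) as exc:
            raise type(exc)(f"record {rid}: {exc}") from exc
        row = fv.as_dict()
        row["source_id"] = rid
        row["label"] = rec.label
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[["source_id", "label", *FEATURE_COLUMNS]]
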