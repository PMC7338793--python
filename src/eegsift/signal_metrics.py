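"""Decomposition/reconstruction quality indexes: Pr, SNR and MAE.

Pr is the Pearson correlation coefficient between the raw and processed
series, SNR the signal-to-noise ratio in dB with the raw series as
reference, and MAE the mean absolute error in the signal's units (uV for
EEG).  A perfect reconstruction has Pr = 1, MAE = 0 and infinite SNR; the
infinity is reported as a float('inf') sentinel rather than an error so
summary tables can carry it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .decomposition import IMFSet
from .errors import ValidationError


@dataclass
class EvaluationIndexes:
    pr: float
    snr: float
    mae: float

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.pr <= 1.0 + 1e-12:
            raise ValidationError("pr must lie in [-1, 1]")
        if self.mae < 0:
            raise ValidationError("mae must be non-negative")


@dataclass
class DecompositionEvaluation:
    """Per-IMF indexes against the raw signal plus their arithmetic means."""

    per_imf: dict[int, EvaluationIndexes]
    averages: EvaluationIndexes


def _as_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be 1-D and of equal length")
    return x, y


def pearson_pr(x, y) -> float:
    """Pearson correlation coefficient of two equal-length series."""
    x, y = _as_pair(x, y)
    if x.size < 2:
        raise ValidationError("need at least 2 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if denom == 0.0:
        raise ValidationError("correlation undefined for constant input")
    return float(dx @ dy) / denom


def snr_db(x, y) -> float:
    """10*log10( sum(x^2) / sum((x-y)^2) ), x the reference series."""
    x, y = _as_pair(x, y)
    num = float(x @ x)
    if num == 0.0:
        raise ValidationError("SNR undefined for an all-zero reference")
    err = x - y
    den = float(err @ err)
    if den == 0.0:
        return math.inf
    return 10.0 * math.log10(num / den)


def mae(x, y) -> float:
    """Mean absolute error between two equal-length series."""
    x, y = _as_pair(x, y)
    if x.size < 1:
        raise ValidationError("need at least 1 sample")
    return float(np.mean(np.abs(x - y)))


def evaluate_reconstruction(raw, reconstructed) -> EvaluationIndexes:
    """The three indexes of a reconstructed series against the raw one."""
    return EvaluationIndexes(
        pr=pearson_pr(raw, reconstructed),
        snr=snr_db(raw, reconstructed),
        mae=mae(raw, reconstructed),
    )


def evaluate_decomposition(imfset: IMFSet, raw) -> DecompositionEvaluation:
    """Indexes of every IMF against the raw signal, plus their means.

    Constant (zero-padded) components have undefined correlation; they are
    scored pr = 0 so dataset-level averaging stays defined, mirroring the
    treatment in IMF selection.
    """
    raw = np.asarray(raw, dtype=float)
    per: dict[int, EvaluationIndexes] = {}
    for j in range(imfset.n_imfs):
        comp = imfset.imfs[j]
        try:
            pr = pearson_pr(raw, comp)
        except ValidationError:
            pr = 0.0
        per[j + 1] = EvaluationIndexes(pr=pr, snr=snr_db(raw, comp), mae=mae(raw, comp))
    avg = EvaluationIndexes(
        pr=float(np.mean([e.pr for e in per.values()])),
        snr=float(np.mean([e.snr for e in per.values()])),
        mae=float(np.mean([e.mae for e in per.values()])),
    )
    return DecompositionEvaluation(per_imf=per, averages=avg)
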