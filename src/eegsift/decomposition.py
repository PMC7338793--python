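"""Empirical mode decomposition and its noise-assisted ensemble variants.

EMD sifts a signal into intrinsic mode functions (IMFs): oscillatory
components whose extrema and zero-crossing counts differ by at most one and
whose local envelope mean is near zero.  Each sifting pass subtracts the
mean of the upper and lower cubic-spline envelopes; passes stop when the
classical pointwise criterion SD = sum_t (h_prev(t) - h(t))^2 / h_prev(t)^2
falls below a threshold or after ``max_siftings`` passes.  In practice the
cap binds on broadband signals, so it acts as a fixed sifting count; the
default of 15 keeps the IMF oscillation property (extrema and
zero-crossing counts within one of each other) while keeping noise
ensembles affordable.

EEMD averages the per-index IMFs of EMD applied to many noise-perturbed
copies of the signal.  CEEMD adds each white-noise realization with both
signs ("complementary pairs"), decomposes both S+N_i and S-N_i, and averages
all 2m decompositions:

    C_j(t) = 1/(2m) * sum_i [ I_{+ij}(t) + I_{-ij}(t) ]

so the injected noise cancels exactly in the reconstruction sum, which is
the variant's advantage over plain EEMD.

IMF selection keeps components whose Pearson correlation with the raw
signal (averaged across records when a whole dataset is decomposed) reaches
a threshold, and reconstruction sums the kept components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import MonotoneRemainder, NoInformativeIMFs, ValidationError


@dataclass
class DecompositionConfig:
    """Knobs of the sifting cascade and the noise ensembles.

    noise_ratio is the added-noise standard deviation as a fraction of the
    signal's; the classical guidance bounds it to at most half.
    ensemble_pairs is the number m of complementary noise pairs (CEEMD runs
    2m EMDs per signal; EEMD runs m).
    """

    noise_ratio: float = 0.2
    ensemble_pairs: int = 100
    n_imfs: int = 9
    max_siftings: int = 15
    sift_sd_threshold: float = 0.2
    boundary_extrema: int = 2

    def __post_init__(self):
        if not (0 <= self.noise_ratio <= 0.5):
            raise ValidationError("noise_ratio must be in [0, 0.5]")
        if self.ensemble_pairs < 1 or self.n_imfs < 1 or self.max_siftings < 1:
            raise ValidationError("ensemble_pairs, n_imfs, max_siftings must be >= 1")
        if self.boundary_extrema < 1:
            raise ValidationError("boundary_extrema must be >= 1")


@dataclass
class IMFSet:
    """Ordered IMFs (high to low frequency) plus the residual trend.

    ``imfs`` is an (n_imfs, source_length) array.  When the sifting cascade
    exhausts before reaching the configured component count, the remaining
    rows are zero and ``n_natural`` records how many are genuine, so that
    per-index ensemble averaging stays well defined.
    """

    imfs: np.ndarray
    residual: np.ndarray
    n_natural: int

    def __post_init__(self):
        self.imfs = np.atleast_2d(np.asarray(self.imfs, dtype=float))
        self.residual = np.asarray(self.residual, dtype=float)
        if self.imfs.shape[1] != self.residual.size:
            raise ValidationError("IMF rows and residual must share length")

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    @property
    def source_length(self) -> int:
        return int(self.residual.size)

    def reconstruct_full(self) -> np.ndarray:
        """Sum of all components plus residual (equals the input for plain EMD)."""
        return self.imfs.sum(axis=0) + self.residual


@dataclass
class ImfSelection:
    """Result of correlation-thresholded IMF screening (1-based indices)."""

    selected_indices: list[int]
    correlations: np.ndarray
    threshold: float = 0.1

    def __post_init__(self):
        self.correlations = np.asarray(self.correlations, dtype=float)
        if not self.selected_indices:
            raise NoInformativeIMFs(
                f"no IMF reached the correlation threshold {self.threshold}"
            )
        for j in self.selected_indices:
            if not 1 <= j <= self.correlations.size:
                raise ValidationError(f"IMF index {j} out of range")


class SiftResult(NamedTuple):
    imf: np.ndarray
    remainder: np.ndarray
    monotone: bool


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima.

    A plateau (flat run) bounded by lower (higher) neighbours contributes a
    single extremum at its floor-midpoint index.  Endpoints never count.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 samples to locate extrema")
    s = np.sign(np.diff(x))
    nz = np.flatnonzero(s)
    empty = np.array([], dtype=int)
    if nz.size < 2:
        return empty, empty
    ss = s[nz]
    chg = np.flatnonzero(ss[:-1] != ss[1:])
    if chg.size == 0:
        return empty, empty
    left = nz[chg] + 1          # first sample of the plateau (or the peak itself)
    right = nz[chg + 1]         # last sample of the plateau
    mid = (left + right) // 2
    return mid[ss[chg] > 0], mid[ss[chg] < 0]


def _extend_extrema(
    idx: np.ndarray, val: np.ndarray, n: int, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to k extrema about each end of the record."""
    kl = min(k, idx.size)
    left_i = -idx[:kl][::-1]
    left_v = val[:kl][::-1]
    right_i = 2 * (n - 1) - idx[-kl:][::-1]
    right_v = val[-kl:][::-1]
    xi = np.concatenate([left_i, idx, right_i])
    vi = np.concatenate([left_v, val, right_v])
    xi, keep = np.unique(xi, return_index=True)
    return xi, vi[keep]


def envelope_mean(x: np.ndarray, boundary_extrema: int = 2) -> np.ndarray:
    """Mean of the upper and lower cubic-spline envelopes of x.

    Envelopes interpolate the (mirror-extended) maxima and minima.  Raises
    :class:`MonotoneRemainder` when fewer than two maxima or two minima
    exist even after extension — the caller treats x as a finished trend.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        raise MonotoneRemainder("fewer than two maxima/minima; remainder is a trend")
    t = np.arange(n)
    mi, mv = _extend_extrema(maxima, x[maxima], n, boundary_extrema)
    ni, nv = _extend_extrema(minima, x[minima], n, boundary_extrema)
    bc = "not-a-knot"
    upper = CubicSpline(mi, mv, bc_type=bc if mi.size >= 4 else "natural")(t)
    lower = CubicSpline(ni, nv, bc_type=bc if ni.size >= 4 else "natural")(t)
    return 0.5 * (upper + lower)


def sift_imf(x: np.ndarray, config: DecompositionConfig | None = None) -> SiftResult:
    """Extract one IMF from x by iterative envelope-mean subtraction.

    Stops when the pointwise SD criterion falls below
    ``sift_sd_threshold`` or after ``max_siftings`` passes.  A monotone
    (or constant) input yields a zero IMF, the input as remainder, and the
    ``monotone`` completion flag.
    """
    config = config or DecompositionConfig()
    x = np.asarray(x, dtype=float)
    h = x.copy()
    for _ in range(config.max_siftings):
        try:
            m = envelope_mean(h, config.boundary_extrema)
        except MonotoneRemainder:
            if np.array_equal(h, x):
                return SiftResult(np.zeros_like(x), x.copy(), True)
            break
        nz = h != 0.0
        if not np.any(nz):
            return SiftResult(np.zeros_like(x), x.copy(), True)
        sd = float(np.sum(m[nz] * m[nz] / (h[nz] * h[nz])))
        h = h - m
        if sd < config.sift_sd_threshold:
            break
    return SiftResult(h, x - h, False)


def emd(x: np.ndarray, config: DecompositionConfig | None = None) -> IMFSet:
    """Plain empirical mode decomposition.

    Sifts the running remainder until ``n_imfs`` components are extracted or
    the remainder is monotone/constant; missing components are zero-padded
    so the set always holds exactly ``n_imfs`` rows.  The telescoping
    construction makes sum(IMFs) + residual reproduce the input exactly.
    """
    config = config or DecompositionConfig()
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValidationError("signal must have at least 16 samples")
    imfs = np.zeros((config.n_imfs, x.size))
    remainder = x.copy()
    n_natural = 0
    for j in range(config.n_imfs):
        res = sift_imf(remainder, config)
        if res.monotone:
            break
        imfs[j] = res.imf
        remainder = res.remainder
        n_natural += 1
    return IMFSet(imfs=imfs, residual=remainder, n_natural=n_natural)


def _noise_scale(x: np.ndarray, config: DecompositionConfig) -> float:
    return config.noise_ratio * float(np.std(x))


def eemd(
    x: np.ndarray,
    config: DecompositionConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> IMFSet:
    """Ensemble EMD: average EMDs of independently noise-perturbed copies.

    Uses ``ensemble_pairs`` single noise draws with standard deviation
    ``noise_ratio * std(x)``.  With noise_ratio = 0 every member is the
    plain EMD, so that result is returned directly.
    """
    config = config or DecompositionConfig()
    x = np.asarray(x, dtype=float)
    scale = _noise_scale(x, config)
    if scale == 0.0:
        return emd(x, config)
    rng = np.random.default_rng(rng)
    acc_imfs = np.zeros((config.n_imfs, x.size))
    acc_res = np.zeros(x.size)
    n_nat = 0
    for _ in range(config.ensemble_pairs):
        noise = scale * rng.standard_normal(x.size)
        d = emd(x + noise, config)
        acc_imfs += d.imfs
        acc_res += d.residual
        n_nat = max(n_nat, d.n_natural)
    m = config.ensemble_pairs
    return IMFSet(imfs=acc_imfs / m, residual=acc_res / m, n_natural=n_nat)


def ceemd(
    x: np.ndarray,
    config: DecompositionConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> IMFSet:
    """Complementary-ensemble EMD with paired opposite-sign noise.

    For each of the m pairs one Gaussian white-noise series N_i is drawn and
    both S + N_i and S - N_i are decomposed; per-index components are
    averaged over all 2m decompositions.  Because EMD is complete, the noise
    cancels exactly in sum(IMFs) + residual, so the reconstruction error is
    at machine precision — the advantage over plain EEMD.
    """
    config = config or DecompositionConfig()
    x = np.asarray(x, dtype=float)
    scale = _noise_scale(x, config)
    if scale == 0.0:
        return emd(x, config)
    rng = np.random.default_rng(rng)
    acc_imfs = np.zeros((config.n_imfs, x.size))
    acc_res = np.zeros(x.size)
    n_nat = 0
    for _ in range(config.ensemble_pairs):
        noise = scale * rng.standard_normal(x.size)
        for signed in (x + noise, x - noise):
            d = emd(signed, config)
            acc_imfs += d.imfs
            acc_res += d.residual
            n_nat = max(n_nat, d.n_natural)
    m2 = 2 * config.ensemble_pairs
    return IMFSet(imfs=acc_imfs / m2, residual=acc_res / m2, n_natural=n_nat)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, with 0 for degenerate (constant) components."""
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def select_imfs(
    imfsets: Sequence[IMFSet] | IMFSet,
    raws: Sequence[np.ndarray] | np.ndarray,
    threshold: float = 0.1,
) -> ImfSelection:
    """Correlation-thresholded IMF screening.

    Computes the Pearson correlation of every IMF with its raw signal, per
    record, averages across records per IMF index, and keeps the 1-based
    indices whose average reaches ``threshold``.  Constant (e.g. padded)
    components contribute correlation 0.  Raises :class:`NoInformativeIMFs`
    when the selection is empty.
    """
    if isinstance(imfsets, IMFSet):
        imfsets = [imfsets]
        raws = [np.asarray(raws, dtype=float)]
    if len(imfsets) != len(raws):
        raise ValidationError("imfsets and raws must be aligned")
    n_imfs = {s.n_imfs for s in imfsets}
    if len(n_imfs) != 1:
        raise ValidationError("all IMFSets must share n_imfs")
    n = n_imfs.pop()
    corr = np.zeros(n)
    for s, raw in zip(imfsets, raws):
        raw = np.asarray(raw, dtype=float)
        for j in range(n):
            corr[j] += _safe_corr(s.imfs[j], raw)
    corr /= len(imfsets)
    selected = [j + 1 for j in range(n) if corr[j] >= threshold]
    return ImfSelection(selected_indices=selected, correlations=corr, threshold=threshold)


def reconstruct(imfset: IMFSet, selection: ImfSelection) -> np.ndarray:
    """Elementwise sum of the selected IMFs (residual excluded)."""
    for j in selection.selected_indices:
        if not 1 <= j <= imfset.n_imfs:
            raise ValidationError(f"selected IMF index {j} out of range")
    idx = [j - 1 for j in selection.selected_indices]
    return imfset.imfs[idx].sum(axis=0)
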