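"""Reading Bonn-format EEG text files and generating synthetic two-class EEG.

The Bonn epilepsy database distributes each single-channel recording as a
plain-text file with one integer amplitude sample (microvolts) per line:
4,097 samples at 173.61 Hz, band-pass filtered to 0.53-40 Hz.  The reader
here accepts any whitespace-tolerant one-number-per-line file.

The synthetic generator emulates the two classes the recognition pipeline
discriminates:

* interictal-like records: band-limited Gaussian noise of modest amplitude
  (default range target -252..123 uV, the per-record range of a typical
  between-seizure channel);
* ictal-like records: a high-amplitude ~3 Hz spike-wave rhythm with
  harmonics and sharpened peaks riding on band-limited noise (default range
  target -890..1367 uV).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .errors import EmptyDatasetError, ParseError, ValidationError

BONN_SAMPLING_RATE_HZ = 173.61
BONN_N_SAMPLES = 4097

VALID_LABELS = frozenset(
    {"interictal", "ictal", "healthy_open", "healthy_closed", "hippocampal", "unlabeled"}
)


@dataclass
class EEGRecord:
    """One single-channel EEG trace with sampling metadata and a class tag."""

    samples: np.ndarray
    sampling_rate: float = BONN_SAMPLING_RATE_HZ
    label: str = "unlabeled"
    source_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 16:
            raise ValidationError("EEGRecord needs a 1-D series of at least 16 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("EEGRecord samples must be finite")
        if not self.sampling_rate > 0:
            raise ValidationError("sampling_rate must be positive")
        if self.label not in VALID_LABELS:
            raise ValidationError(f"unknown label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)


@dataclass
class DatasetBundle:
    """Ordered collection of EEGRecords sharing one sampling rate."""

    records: list[EEGRecord]

    def __post_init__(self):
        if self.records:
            rates = {r.sampling_rate for r in self.records}
            if len(rates) > 1:
                raise ValidationError(f"records mix sampling rates: {sorted(rates)}")

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass
class SyntheticConfig:
    """Parameters of the two-class synthetic EEG generator.

    Amplitude targets are the per-record (min, max) in microvolts that each
    generated record is affinely rescaled toward; they default to the ranges
    of representative interictal and ictal Bonn channels.  ``amplitude_jitter``
    scatters the per-record targets multiplicatively so records are not
    range-identical (real channels vary); 0 disables it.
    """

    n_per_class: int = 100
    n_samples: int = BONN_N_SAMPLES
    seed: int = 0
    sampling_rate: float = BONN_SAMPLING_RATE_HZ
    interictal_amplitude: tuple[float, float] = (-252.0, 123.0)
    ictal_amplitude: tuple[float, float] = (-890.0, 1367.0)
    ictal_rhythm_hz: float = 3.0
    band: tuple[float, float] = (0.53, 40.0)
    spike_sharpness: float = 2.0
    amplitude_jitter: float = 0.1

    def __post_init__(self):
        if self.n_per_class < 1 or self.n_samples < 16:
            raise ValidationError("n_per_class >= 1 and n_samples >= 16 required")
        for lo, hi in (self.interictal_amplitude, self.ictal_amplitude):
            if not lo < hi:
                raise ValidationError("amplitude low must be < high")
        lo, hi = self.band
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValidationError("band must lie inside (0, sampling_rate/2)")
        if not (0 <= self.amplitude_jitter < 0.5):
            raise ValidationError("amplitude_jitter must be in [0, 0.5)")


def read_bonn_file(path: str | os.PathLike) -> EEGRecord:
    """Read one Bonn-style text file (one numeric amplitude per line).

    Leading/trailing whitespace and CRLF line endings are tolerated; blank
    trailing lines are ignored.  The record comes back with
    ``label='unlabeled'`` and the Bonn sampling rate.
    """
    path = Path(path)
    with open(path, "r") as fh:
        lines = fh.readlines()
    values: list[float] = []
    for lineno, line in enumerate(lines, start=1):
        token = line.strip()
        if not token:
            if any(l.strip() for l in lines[lineno:]):
                raise ParseError(f"{path}: blank line {lineno} inside data", path, lineno)
            break
        try:
            values.append(float(token))
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric value {token!r} at line {lineno}", path, lineno
            ) from None
    if not values:
        raise ParseError(f"{path}: file contains no samples", path, None)
    return EEGRecord(
        samples=np.array(values, dtype=float),
        sampling_rate=BONN_SAMPLING_RATE_HZ,
        label="unlabeled",
        source_id=path.stem,
    )


def write_bonn_file(record: EEGRecord, path: str | os.PathLike) -> None:
    """Write a record in Bonn layout (one sample per line).

    Integer-valued amplitudes are written as integers so a write/read
    round-trip is exact for 12-bit A/D data.
    """
    with open(path, "w") as fh:
        for v in record.samples:
            v = float(v)
            fh.write(f"{int(v)}\n" if v.is_integer() else f"{v!r}\n")


def load_dataset(
    directory: str | os.PathLike, labels: Mapping[str, str]
) -> DatasetBundle:
    """Scan a directory of Bonn-style files into a labeled bundle.

    ``labels`` maps a subdirectory name or a filename prefix to a class
    label.  Files are visited in lexicographic filename order (full relative
    path), so the bundle order is independent of filesystem enumeration.
    """
    directory = Path(directory)
    for lab in labels.values():
        if lab not in VALID_LABELS:
            raise ValidationError(f"unknown label {lab!r} in mapping")
    paths = sorted(p for p in directory.rglob("*") if p.is_file())
    records = []
    for p in paths:
        rel = p.relative_to(directory)
        label = None
        for key, lab in labels.items():
            if key in rel.parts[:-1] or p.name.startswith(key):
                label = lab
                break
        if label is None:
            continue
        rec = read_bonn_file(p)
        rec.label = label
        records.append(rec)
    if not records:
        raise EmptyDatasetError(f"no files under {directory} matched the label mapping")
    return DatasetBundle(records=records)


def _bandlimited_noise(n: int, fs: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    """Zero-phase band-pass filtered Gaussian white noise, unit-ish scale."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    padlen = min(n - 1, 3 * (2 * sos.shape[0] + 1))
    return sps.sosfiltfilt(sos, white, padlen=padlen)


def _rescale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Affine map of the empirical min/max of x onto (lo, hi)."""
    xmin, xmax = x.min(), x.max()
    if xmax == xmin:
        return np.full_like(x, 0.5 * (lo + hi))
    return lo + (x - xmin) * (hi - lo) / (xmax - xmin)


def generate_synthetic_record(
    class_label: str, config: SyntheticConfig, rng: np.random.Generator
) -> EEGRecord:
    """Generate one synthetic EEG record of the requested class.

    interictal: band-limited Gaussian noise rescaled toward the interictal
    amplitude targets.  ictal: an amplitude-modulated spike-wave rhythm at
    ``ictal_rhythm_hz`` -- a sharpened sinusoid (signed power, exponent
    ``spike_sharpness``) plus weaker 2nd/3rd harmonics -- on top of
    band-limited noise, rescaled toward the ictal targets.
    """
    if class_label not in ("interictal", "ictal"):
        raise ValidationError("class_label must be 'interictal' or 'ictal'")
    n, fs = config.n_samples, config.sampling_rate
    t = np.arange(n) / fs
    jit = config.amplitude_jitter

    if class_label == "interictal":
        x = _bandlimited_noise(n, fs, config.band, rng)
        lo, hi = config.interictal_amplitude
    else:
        f0 = config.ictal_rhythm_hz
        phase = rng.uniform(0, 2 * np.pi)
        base = np.sin(2 * np.pi * f0 * t + phase)
        spike = np.sign(base) * np.abs(base) ** config.spike_sharpness
        rhythm = (
            spike
            + 0.30 * np.sin(2 * np.pi * 2 * f0 * t + rng.uniform(0, 2 * np.pi))
            + 0.15 * np.sin(2 * np.pi * 3 * f0 * t + rng.uniform(0, 2 * np.pi))
        )
        # slow burst-like envelope; keeps the spectral peak at f0 dominant
        envelope = 1.0 + 0.3 * np.sin(2 * np.pi * 0.15 * t + rng.uniform(0, 2 * np.pi))
        noise = _bandlimited_noise(n, fs, config.band, rng)
        noise /= max(np.abs(noise).max(), np.finfo(float).tiny)
        x = envelope * rhythm + 0.15 * noise
        lo, hi = config.ictal_amplitude
    if jit > 0:
        lo = lo * (1 + rng.uniform(-jit, jit))
        hi = hi * (1 + rng.uniform(-jit, jit))
    samples = _rescale(x, lo, hi)
    return EEGRecord(
        samples=samples,
        sampling_rate=fs,
        label=class_label,
        source_id=f"synthetic-{class_label}",
    )


def generate_synthetic_dataset(config: SyntheticConfig) -> DatasetBundle:
    """Generate ``n_per_class`` records per class, deterministically.

    Each record draws from its own rng stream spawned from ``config.seed``
    via a (class, index) spawn key, so generation order cannot change the
    data and the bundle is a pure function of the config.
    """
    records = []
    for ci, label in enumerate(("interictal", "ictal")):
        for k in range(config.n_per_class):
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(ci, k))
            rec = generate_synthetic_record(label, config, np.random.default_rng(ss))
            rec.source_id = f"{label}-{k:03d}"
            records.append(rec)
    return DatasetBundle(records=records)


def write_dataset(bundle: DatasetBundle, directory: str | os.PathLike) -> Path:
    """Write a bundle as Bonn-style files plus a CSV manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(bundle.records):
        name = f"{rec.source_id or 'record-%03d' % i}.txt"
        write_bonn_file(rec, directory / name)
        rows.append((name, rec.label, rec.n_samples))
    manifest = directory / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write("filename,label,n_samples\n")
        for name, label, n in rows:
            fh.write(f"{name},{label},{n}\n")
    return manifest
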