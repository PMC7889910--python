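"""Spectrum containers, plain-text I/O and the synthetic breath-spectrum cohort generator.

A breath sample is represented as a Raman-like spectrum: an ordered axis of
wavenumber-style positions (a unitless ordered axis by convention called cm^-1)
with one intensity per position.  The study's real breath data are not publicly
deposited, so :func:`generate_cohort` emulates their stated structure — smooth
class-dependent vibrational bands, a slowly varying baseline, additive Gaussian
noise, and rare narrow positive spike artifacts — with the published cohort
sizes (55 early gastric cancer, 89 advanced gastric cancer, 56 healthy).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClassLabel",
    "Spectrum",
    "LabeledSpectrumSet",
    "SyntheticCohortConfig",
    "read_spectrum",
    "write_spectrum",
    "generate_spectrum",
    "generate_cohort",
    "read_cohort",
    "write_cohort",
    "DEFAULT_BAND_LIBRARY",
]


class ClassLabel(enum.IntEnum):
    """Diagnostic class with its fixed integer code (EGC=0, AGC=1, HEALTHY=2)."""

    EGC = 0
    AGC = 1
    HEALTHY = 2

    @classmethod
    def from_name(cls, name: str) -> "ClassLabel":
        try:
            return cls[str(name).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown class label {name!r}; expected one of "
                             f"{[m.name for m in cls]}") from None


@dataclass
class Spectrum:
    """One breath sample: strictly increasing axis with finite intensities."""

    axis: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("axis and intensity must be 1-D")
        if self.axis.size != self.intensity.size:
            raise ValueError(
                f"axis ({self.axis.size}) and intensity ({self.intensity.size}) "
                "must have equal length")
        if self.axis.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.axis)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("axis and intensity must be finite")
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")

    def __len__(self) -> int:
        return self.axis.size

    def replace(self, **updates) -> "Spectrum":
        """Copy with selected fields replaced; meta is shallow-copied."""
        fields = dict(axis=self.axis.copy(), intensity=self.intensity.copy(),
                      sample_id=self.sample_id, meta=dict(self.meta))
        fields.update(updates)
        return Spectrum(**fields)


@dataclass
class LabeledSpectrumSet:
    """A cohort: spectra and class labels aligned by index, unique sample ids."""

    spectra: list[Spectrum]
    labels: list[ClassLabel]

    def __post_init__(self) -> None:
        if len(self.spectra) != len(self.labels):
            raise ValueError("spectra and labels must have the same length")
        self.labels = [ClassLabel(l) for l in self.labels]
        ids = [s.sample_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[tuple[Spectrum, ClassLabel]]:
        return iter(zip(self.spectra, self.labels))

    def subset(self, indices: Sequence[int]) -> "LabeledSpectrumSet":
        return LabeledSpectrumSet([self.spectra[i] for i in indices],
                                  [self.labels[i] for i in indices])

    @property
    def label_codes(self) -> np.ndarray:
        return np.array([int(l) for l in self.labels], dtype=int)


# ---------------------------------------------------------------------------
# Text I/O: two-column delimited text, "# key=value" comment lines for metadata.
# ---------------------------------------------------------------------------

def _parse_meta_value(raw: str):
    try:
        return json.loads(raw)
    except (json.JSONDecodeError, ValueError):
        return raw


def read_spectrum(path) -> Spectrum:
    """Read a two-column (position, intensity) text file; header optional.

    Rows with non-numeric fields are skipped (headers), ``# key=value`` lines
    populate ``meta``, and the axis is sorted ascending on load.  Duplicate axis
    values are an error naming the offending value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = _parse_meta_value(val.strip())
            continue
        for sep in (",", "\t", ";"):
            if sep in line:
                parts = line.split(sep)
                break
        else:
            parts = line.split()
        if len(parts) < 2:
            continue
        try:
            x, y = float(parts[0]), float(parts[1])
        except ValueError:
            continue  # header or malformed row
        xs.append(x)
        ys.append(y)
    if len(xs) < 2:
        raise ValueError(f"{path}: fewer than 2 valid data rows")
    axis = np.array(xs)
    order = np.argsort(axis, kind="stable")
    axis = axis[order]
    dupes = axis[:-1][np.diff(axis) == 0]
    if dupes.size:
        raise ValueError(f"{path}: duplicate axis value {dupes[0]!r}")
    sample_id = meta.pop("sample_id", path.stem)
    return Spectrum(axis=axis, intensity=np.array(ys)[order],
                    sample_id=str(sample_id), meta=meta)


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as CSV with full float precision (lossless round trip)."""
    path = Path(path)
    lines = [f"# sample_id={spectrum.sample_id}"]
    for key, val in spectrum.meta.items():
        lines.append(f"# {key}={json.dumps(val) if not isinstance(val, str) else val}")
    lines.append("wavenumber,intensity")
    for x, y in zip(spectrum.axis, spectrum.intensity):
        lines.append(f"{float(x)!r},{float(y)!r}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic cohort generator.
# ---------------------------------------------------------------------------

# Shared band centers/widths with class-dependent mean amplitudes.  Centers sit
# in the 400-1500 cm^-1 window; widths are Gaussian sigmas in axis units (~13
# points at the default 1200-point sampling, so far broader than any spike).
# Entries are (center, width, mean_amplitude, amplitude_spread).
_CENTERS = (520.0, 640.0, 750.0, 870.0, 1000.0, 1090.0, 1210.0, 1320.0, 1440.0)
_WIDTH = 12.0
_SPREAD = 0.05
_AMPLITUDES = {
    ClassLabel.EGC:     (0.70, 0.60, 0.50, 0.50, 1.00, 0.80, 0.45, 0.60, 0.60),
    ClassLabel.AGC:     (0.40, 0.90, 0.35, 0.80, 0.80, 1.20, 0.30, 0.90, 0.40),
    ClassLabel.HEALTHY: (1.00, 0.30, 0.80, 0.30, 1.20, 0.40, 0.60, 0.30, 0.90),
}
DEFAULT_BAND_LIBRARY: dict[ClassLabel, tuple[tuple[float, float, float, float], ...]] = {
    label: tuple((c, _WIDTH, a, _SPREAD) for c, a in zip(_CENTERS, amps))
    for label, amps in _AMPLITUDES.items()
}


@dataclass
class SyntheticCohortConfig:
    """Stated world of the synthetic generator (cohort sizes per the study)."""

    n_egc: int = 55
    n_agc: int = 89
    n_healthy: int = 56
    n_points: int = 1200
    axis_range: tuple[float, float] = (400.0, 1500.0)
    band_library: Mapping[ClassLabel, Sequence[tuple[float, float, float, float]]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_LIBRARY))
    band_shape: str = "gaussian"  # or "lorentzian"
    baseline_order: int = 2
    baseline_scale: float = 0.15
    noise_sd: float = 0.02
    spike_rate: float = 0.3
    spike_width_max: int = 3
    spike_amplitude_range: tuple[float, float] = (1.5, 4.0)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_egc, self.n_agc, self.n_healthy) < 0:
            raise ValueError("cohort counts must be >= 0")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.axis_range[1] <= self.axis_range[0]:
            raise ValueError("axis_range must be increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if self.band_shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band_shape {self.band_shape!r}")
        if self.spike_width_max < 1:
            raise ValueError("spike_width_max must be >= 1")
        step = (self.axis_range[1] - self.axis_range[0]) / (self.n_points - 1)
        narrowest = min(band[1] / step
                        for bands in self.band_library.values() for band in bands)
        if self.spike_width_max >= narrowest:
            raise ValueError(
                f"spike_width_max ({self.spike_width_max} points) must be smaller "
                f"than the narrowest band width ({narrowest:.1f} points): spikes "
                "must stay much narrower than genuine bands")

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.axis_range[0], self.axis_range[1], self.n_points)


def _band_profile(axis: np.ndarray, center: float, width: float,
                  amplitude: float, shape: str) -> np.ndarray:
    if shape == "gaussian":
        return amplitude * np.exp(-0.5 * ((axis - center) / width) ** 2)
    # Lorentzian: width is the half-width at half maximum
    return amplitude / (1.0 + ((axis - center) / width) ** 2)


def band_sum(label: ClassLabel, config: SyntheticCohortConfig,
             amplitudes: Sequence[float] | None = None) -> np.ndarray:
    """Noise-free sum of the class's band profiles (the generation ground truth)."""
    axis = config.axis
    out = np.zeros_like(axis)
    bands = config.band_library[ClassLabel(label)]
    for i, (center, width, mean_amp, _spread) in enumerate(bands):
        amp = mean_amp if amplitudes is None else amplitudes[i]
        out += _band_profile(axis, center, width, amp, config.band_shape)
    return out


def generate_spectrum(label: ClassLabel, config: SyntheticCohortConfig,
                      rng: np.random.Generator) -> Spectrum:
    """Draw one synthetic spectrum: bands + polynomial baseline + noise + spikes."""
    config.validate()
    label = ClassLabel(label)
    axis = config.axis
    bands = config.band_library[label]
    amps = np.array([rng.normal(a, s) for (_c, _w, a, s) in bands]).clip(min=0.0)
    signal = band_sum(label, config, amplitudes=amps)

    # smooth baseline drift: random low-order polynomial on the normalized axis
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    baseline = np.zeros_like(axis)
    for k in range(config.baseline_order + 1):
        lo = 0.0 if k == 0 else -config.baseline_scale
        baseline += rng.uniform(lo, config.baseline_scale) * t ** k

    noise = rng.normal(0.0, config.noise_sd, size=axis.size) if config.noise_sd else 0.0

    # rare narrow positive spikes (cosmic-ray-like): Poisson count, triangular
    # shape, full width (2*hw - 1) <= spike_width_max points
    spikes = np.zeros_like(axis)
    n_spikes = int(rng.poisson(config.spike_rate)) if config.spike_rate else 0
    max_hw = max(1, (config.spike_width_max + 1) // 2)
    max_band_amp = max(b[2] for b in bands)
    for _ in range(n_spikes):
        pos = int(rng.integers(0, axis.size))
        hw = int(rng.integers(1, max_hw + 1))
        amp = rng.uniform(*config.spike_amplitude_range) * max_band_amp
        for off in range(-(hw - 1), hw):
            idx = pos + off
            if 0 <= idx < axis.size:
                spikes[idx] += amp * (1.0 - abs(off) / hw)

    meta = {"label": label.name, "augmented": False, "n_spikes": n_spikes,
            "band_shape": config.band_shape}
    return Spectrum(axis=axis, intensity=signal + baseline + noise + spikes, meta=meta)


def generate_cohort(config: SyntheticCohortConfig) -> LabeledSpectrumSet:
    """Generate the full labeled cohort, reproducible from ``config.seed``.

    Each spectrum uses its own counter-keyed random stream, so reproducibility
    does not depend on generation order.
    """
    config.validate()
    counts = [(ClassLabel.EGC, config.n_egc), (ClassLabel.AGC, config.n_agc),
              (ClassLabel.HEALTHY, config.n_healthy)]
    if sum(n for _l, n in counts) == 0:
        raise ValueError("all cohort counts are zero")
    spectra: list[Spectrum] = []
    labels: list[ClassLabel] = []
    index = 0
    for label, n in counts:
        for i in range(n):
            rng = np.random.default_rng([config.seed, index])
            spec = generate_spectrum(label, config, rng)
            spec.sample_id = f"{label.name}_{i:03d}"
            spectra.append(spec)
            labels.append(label)
            index += 1
    return LabeledSpectrumSet(spectra, labels)


# ---------------------------------------------------------------------------
# Cohort directory I/O (one file per sample + labels.csv).
# ---------------------------------------------------------------------------

def write_cohort(cohort: LabeledSpectrumSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for spec, label in cohort:
        write_spectrum(spec, directory / f"{spec.sample_id}.csv")
        rows.append({"sample_id": spec.sample_id, "label": label.name})
    pd.DataFrame(rows).to_csv(directory / "labels.csv", index=False)


def read_cohort(directory) -> LabeledSpectrumSet:
    directory = Path(directory)
    table_path = directory / "labels.csv"
    if not table_path.exists():
        raise FileNotFoundError(f"no labels.csv in {directory}")
    table = pd.read_csv(table_path)
    spectra, labels = [], []
    for _, row in table.iterrows():
        spec = read_spectrum(directory / f"{row['sample_id']}.csv")
        spec.sample_id = str(row["sample_id"])
        spectra.append(spec)
        labels.append(ClassLabel.from_name(row["label"]))
    return LabeledSpectrumSet(spectra, labels)
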