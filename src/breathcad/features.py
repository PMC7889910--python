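"""Data augmentation and 50-peak feature extraction.

Augmentation follows the study's stated rule: crop every spectrum to a fixed
1200-point window, then add a copy shifted right by 2 axis units (linear
re-interpolation onto the original axis).  Feature extraction detects local
maxima on the preprocessed signal, ranks them by prominence, keeps the top
``k`` (default 50), and uses their heights ordered by position as the network's
fixed-length input vector, min-max scaled to [0, 1] with training-set statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .spectra import ClassLabel, LabeledSpectrumSet, Spectrum

__all__ = [
    "Peak",
    "AugmentConfig",
    "FeatureMatrix",
    "crop_spectrum",
    "shift_spectrum",
    "augment_cohort",
    "detect_peaks",
    "select_top_peaks",
    "featurize",
    "PeakFeaturizer",
]


@dataclass
class Peak:
    """One detected band: position, height above baseline, FWHM, area, prominence."""

    position: float
    height: float
    width: float
    area: float
    prominence: float
    placeholder: bool = False


@dataclass
class AugmentConfig:
    crop_length: int = 1200
    shift_amount: float = 2.0
    directions: tuple[str, ...] = ("right",)

    def validate(self) -> None:
        if self.crop_length < 2:
            raise ValueError("crop_length must be >= 2")
        if self.shift_amount < 0:
            raise ValueError("shift_amount must be >= 0")
        unknown = set(self.directions) - {"right", "left"}
        if unknown:
            raise ValueError(f"unknown shift directions: {sorted(unknown)}")


@dataclass
class FeatureMatrix:
    """n_samples x k table of scaled peak heights with per-feature scaling stats."""

    values: np.ndarray
    sample_ids: list[str]
    labels: list[ClassLabel]
    feature_names: list[str]
    scale_min: np.ndarray
    scale_max: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaN")
        n, k = self.values.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels must match the number of rows")
        if len(self.feature_names) != k:
            raise ValueError("feature_names must match the number of columns")

    @property
    def label_codes(self) -> np.ndarray:
        return np.array([int(l) for l in self.labels], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", [l.name for l in self.labels])
        df.insert(0, "sample_id", self.sample_ids)
        return df


def crop_spectrum(spectrum: Spectrum, crop_length: int) -> Spectrum:
    """Keep the centered contiguous window of ``crop_length`` points."""
    n = len(spectrum)
    if crop_length > n:
        raise ValueError(f"crop_length {crop_length} exceeds spectrum length {n}")
    start = (n - crop_length) // 2
    stop = start + crop_length
    return spectrum.replace(axis=spectrum.axis[start:stop].copy(),
                            intensity=spectrum.intensity[start:stop].copy())


def shift_spectrum(spectrum: Spectrum, shift_amount: float) -> Spectrum:
    """Shift the signal right by ``shift_amount`` axis units onto the same axis.

    Intensities are re-associated with ``axis + shift`` and linearly resampled
    back onto the original axis; the leading gap is filled with the edge value.
    """
    if shift_amount < 0:
        raise ValueError("shift_amount must be >= 0")
    if shift_amount == 0:
        return spectrum.replace()
    shifted = np.interp(spectrum.axis, spectrum.axis + shift_amount,
                        spectrum.intensity, left=spectrum.intensity[0])
    out = spectrum.replace(intensity=shifted)
    out.meta["augmented"] = True
    out.meta["shift_applied"] = float(shift_amount)
    return out


def augment_cohort(cohort: LabeledSpectrumSet,
                   config: AugmentConfig | None = None) -> LabeledSpectrumSet:
    """Cropped originals plus one shifted copy per configured direction.

    Every output spectrum records its source sample in ``meta['source_id']`` so
    data splitting can keep augmented copies in the same partition as their
    source (leakage guard).
    """
    config = config or AugmentConfig()
    config.validate()
    spectra: list[Spectrum] = []
    labels: list[ClassLabel] = []
    for spec, label in cohort:
        cropped = crop_spectrum(spec, config.crop_length)
        cropped.meta["augmented"] = False
        cropped.meta["source_id"] = spec.sample_id
        spectra.append(cropped)
        labels.append(label)
    for spec, label in cohort:
        cropped = crop_spectrum(spec, config.crop_length)
        for direction in config.directions:
            amount = config.shift_amount
            if direction == "right":
                shifted = shift_spectrum(cropped, amount)
            else:
                shifted = _mirror_shift(cropped, amount)
            shifted.sample_id = f"{spec.sample_id}__shift_{direction}_{amount:g}"
            shifted.meta["augmented"] = True
            shifted.meta["source_id"] = spec.sample_id
            spectra.append(shifted)
            labels.append(label)
    return LabeledSpectrumSet(spectra, labels)


def _mirror_shift(spectrum: Spectrum, amount: float) -> Spectrum:
    # left shift: re-associate intensities with axis - amount, trailing gap edge-filled
    shifted = np.interp(spectrum.axis, spectrum.axis - amount,
                        spectrum.intensity, right=spectrum.intensity[-1])
    out = spectrum.replace(intensity=shifted)
    out.meta["augmented"] = True
    out.meta["shift_applied"] = -float(amount)
    return out


def detect_peaks(spectrum: Spectrum, prominence_floor: float | None = None) -> list[Peak]:
    """Local maxima with prominence above a floor (default 0.5 x intensity sd).

    Width is the full width at half prominence-height via interpolated crossing
    points; area is the trapezoid integral between those crossings.
    """
    if len(spectrum) < 3:
        raise ValueError("spectrum too short for peak detection")
    y = spectrum.intensity
    if prominence_floor is None:
        prominence_floor = 0.5 * float(np.std(y))
        if prominence_floor <= 0:
            prominence_floor = np.finfo(float).tiny
    idx, props = signal.find_peaks(y, prominence=prominence_floor)
    keep = y[idx] > 0
    idx, prominences = idx[keep], props["prominences"][keep]
    if idx.size == 0:
        return []
    widths, _heights, left_ips, right_ips = signal.peak_widths(y, idx, rel_height=0.5)
    grid = np.arange(y.size)
    left_x = np.interp(left_ips, grid, spectrum.axis)
    right_x = np.interp(right_ips, grid, spectrum.axis)
    peaks = []
    for i, peak_idx in enumerate(idx):
        lo = int(np.floor(left_ips[i]))
        hi = int(np.ceil(right_ips[i])) + 1
        area = float(np.trapezoid(y[lo:hi], spectrum.axis[lo:hi]))
        peaks.append(Peak(position=float(spectrum.axis[peak_idx]),
                          height=float(y[peak_idx]),
                          width=float(right_x[i] - left_x[i]),
                          area=max(area, 0.0),
                          prominence=float(prominences[i])))
    return peaks


def select_top_peaks(peaks: Sequence[Peak], k: int = 50) -> list[Peak]:
    """The k most prominent peaks re-ordered by position; zero placeholders pad.

    Ties in prominence are broken in favor of the smaller position.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(peaks, key=lambda p: (-p.prominence, p.position))[:k]
    selected = sorted(ranked, key=lambda p: p.position)
    n_pad = k - len(selected)
    pad = [Peak(position=0.0, height=0.0, width=0.0, area=0.0,
                prominence=0.0, placeholder=True) for _ in range(n_pad)]
    return pad + selected


def _height_vector(spectrum: Spectrum, k: int,
                   prominence_floor: float | None) -> np.ndarray:
    peaks = select_top_peaks(detect_peaks(spectrum, prominence_floor), k)
    return np.array([p.height for p in peaks], dtype=float)


def _height_matrix(spectra: Sequence[Spectrum], k: int,
                   prominence_floor: float | None) -> np.ndarray:
    return np.vstack([_height_vector(s, k, prominence_floor) for s in spectra])


def _fit_minmax(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    flat = hi - lo == 0
    if np.any(flat & (hi == 0)):
        warnings.warn("all-zero feature column(s) scaled to 0", stacklevel=2)
    return lo, hi


def _apply_minmax(raw: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    scaled = (raw - lo) / safe
    return np.where(span == 0, 0.0, scaled)


def featurize(cohort: LabeledSpectrumSet, k: int = 50,
              prominence_floor: float | None = None,
              scaling: tuple[np.ndarray, np.ndarray] | None = None) -> FeatureMatrix:
    """Build the n x k matrix of selected peak heights, min-max scaled to [0, 1].

    When ``scaling`` (min, max per feature) is given, it is applied as-is —
    this is how validation/test cohorts reuse training-set statistics.
    """
    raw = _height_matrix(cohort.spectra, k, prominence_floor)
    lo, hi = scaling if scaling is not None else _fit_minmax(raw)
    return FeatureMatrix(values=_apply_minmax(raw, lo, hi),
                         sample_ids=[s.sample_id for s in cohort.spectra],
                         labels=list(cohort.labels),
                         feature_names=[f"peak_{i+1:02d}" for i in range(k)],
                         scale_min=np.asarray(lo, dtype=float),
                         scale_max=np.asarray(hi, dtype=float))


class PeakFeaturizer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: sequence of preprocessed Spectrum -> (n, k) array.

    ``fit`` learns per-feature min-max statistics from the training spectra;
    ``transform`` applies them unchanged (values for new data may fall slightly
    outside [0, 1] and are deliberately not clipped).
    """

    def __init__(self, k: int = 50, prominence_floor: float | None = None):
        self.k = k
        self.prominence_floor = prominence_floor

    @staticmethod
    def _spectra(X) -> list[Spectrum]:
        return list(X.spectra) if isinstance(X, LabeledSpectrumSet) else list(X)

    def fit(self, X, y=None):
        raw = _height_matrix(self._spectra(X), self.k, self.prominence_floor)
        self.scale_min_, self.scale_max_ = _fit_minmax(raw)
        self.feature_names_ = [f"peak_{i+1:02d}" for i in range(self.k)]
        self.n_features_in_ = self.k
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "scale_min_")
        raw = _height_matrix(self._spectra(X), self.k, self.prominence_floor)
        return _apply_minmax(raw, self.scale_min_, self.scale_max_)
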