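"""Axis cropping and solvent-region exclusion.

Experiment regimes on yam spectra: crop to delta 0.50-9.50 ppm (regime 1),
then additionally excise the solvent residual windows delta 3.28-3.34
(CHD2OD) and 4.6-5.2 (HDO) for regimes 2 and 3.  Excised points are deleted
outright — downstream vectors shorten and the image renderer draws the
retained segments contiguously.  All intervals are closed on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateInputError, ParameterError
from .synth import Dataset, Spectrum

CROP_DEFAULT = (0.50, 9.50)
SOLVENT_EXCLUSIONS = ((3.28, 3.34), (4.6, 5.2))


@dataclass(frozen=True)
class PpmRange:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ParameterError(f"PpmRange requires lo < hi, got ({self.lo}, {self.hi})")

    def contains(self, ppm: np.ndarray) -> np.ndarray:
        return (ppm >= self.lo) & (ppm <= self.hi)

    def overlaps(self, other: "PpmRange") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi


def _as_range(r) -> PpmRange:
    return r if isinstance(r, PpmRange) else PpmRange(*r)


@dataclass(frozen=True)
class PreprocessSpec:
    """Crop window plus a (possibly empty) list of exclusion windows."""

    crop: PpmRange = field(default_factory=lambda: PpmRange(*CROP_DEFAULT))
    exclusions: tuple[PpmRange, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "crop", _as_range(self.crop))
        excl = tuple(_as_range(e) for e in self.exclusions)
        object.__setattr__(self, "exclusions", excl)
        for e in excl:
            if not e.overlaps(self.crop):
                raise ParameterError(
                    f"exclusion ({e.lo}, {e.hi}) does not overlap crop "
                    f"({self.crop.lo}, {self.crop.hi})"
                )
        ordered = sorted(excl, key=lambda e: e.lo)
        for a, b in zip(ordered, ordered[1:]):
            if b.lo <= a.hi:
                raise ParameterError(
                    f"exclusions ({a.lo}, {a.hi}) and ({b.lo}, {b.hi}) overlap"
                )


def experiment_spec(regime: int) -> PreprocessSpec:
    """Regime 1: crop only.  Regimes 2 and 3: crop + solvent exclusions."""
    if regime == 1:
        return PreprocessSpec()
    if regime in (2, 3):
        return PreprocessSpec(exclusions=SOLVENT_EXCLUSIONS)
    raise ParameterError(f"unknown regime {regime}")


def crop_to_range(spectrum: Spectrum, crop: PpmRange | tuple[float, float]) -> Spectrum:
    """Keep exactly the points with lo <= ppm <= hi, order preserved."""
    crop = _as_range(crop)
    mask = crop.contains(spectrum.ppm)
    if not mask.any():
        raise DegenerateInputError(
            f"crop ({crop.lo}, {crop.hi}) leaves no points on axis "
            f"[{spectrum.ppm.min()}, {spectrum.ppm.max()}]"
        )
    return Spectrum(
        spectrum.sample_id, spectrum.ppm[mask], spectrum.intensity[mask], spectrum.label
    )


def exclude_regions(spectrum: Spectrum, exclusions) -> Spectrum:
    """Delete points falling inside any exclusion window (closed intervals)."""
    if len(spectrum) == 0:
        raise DegenerateInputError("empty spectrum")
    drop = np.zeros(len(spectrum), dtype=bool)
    for e in exclusions:
        drop |= _as_range(e).contains(spectrum.ppm)
    if drop.all():
        raise DegenerateInputError("exclusions remove every point")
    keep = ~drop
    return Spectrum(
        spectrum.sample_id, spectrum.ppm[keep], spectrum.intensity[keep], spectrum.label
    )


def apply(spec: PreprocessSpec, dataset: Dataset) -> Dataset:
    """Crop then excise, identically for every spectrum in the dataset."""
    out = []
    for s in dataset.spectra:
        s2 = crop_to_range(s, spec.crop)
        if spec.exclusions:
            s2 = exclude_regions(s2, spec.exclusions)
        out.append(s2)
    return Dataset(out)


class RegionTrimmer(BaseEstimator, TransformerMixin):
    """Column-selecting transformer: crop + exclusions on an intensity matrix.

    Parameters
    ----------
    ppm : array-like
        The shared ppm axis of the input columns.
    crop : (lo, hi)
        Closed crop window in ppm.
    exclusions : sequence of (lo, hi)
        Closed windows to delete (e.g. solvent residuals).

    Attributes
    ----------
    mask_ : ndarray of bool, shape (n_features_in_,)
        Columns retained by transform.
    ppm_out_ : ndarray
        The ppm values of the retained columns.
    """

    def __init__(self, ppm=None, crop=CROP_DEFAULT, exclusions=()):
        self.ppm = ppm
        self.crop = crop
        self.exclusions = exclusions

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.ppm is None:
            raise ParameterError("RegionTrimmer requires the ppm axis")
        ppm = np.asarray(self.ppm, dtype=float)
        if X.ndim != 2 or X.shape[1] != ppm.size:
            raise ParameterError(
                f"X has {X.shape[-1] if X.ndim == 2 else '?'} columns but ppm has {ppm.size}"
            )
        spec = PreprocessSpec(crop=self.crop, exclusions=tuple(self.exclusions))
        keep = spec.crop.contains(ppm)
        for e in spec.exclusions:
            keep &= ~e.contains(ppm)
        if not keep.any():
            raise DegenerateInputError("no columns retained")
        self.n_features_in_ = ppm.size
        self.mask_ = keep
        self.ppm_out_ = ppm[keep]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ParameterError("X column count differs from fit")
        return X[:, self.mask_]
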