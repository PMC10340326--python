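"""Synthetic two-class 1H NMR spectrum generator.

Real geo-authentic and non-authentic Chinese yam spectra share peak
*positions* (the metabolite complement is the same) but differ in peak
*intensity*, most strongly in the sugar region (delta 3.50-6.00 ppm) where
glucose/fructose/sucrose resonate.  The generator reproduces exactly that
structure: a fixed Lorentzian peak table shared by both classes, per-sample
lognormal amplitude jitter (biological concentration spread), a
multiplicative class effect applied to sugar-region peaks of the
non-authentic class, and additive Gaussian baseline noise.

It deliberately does not model J-coupling multiplets, solvent lineshapes,
phase or baseline artifacts, or vendor file formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

GEO_AUTHENTIC = "geo_authentic"
NON_AUTHENTIC = "non_authentic"
LABELS = (GEO_AUTHENTIC, NON_AUTHENTIC)


@dataclass(frozen=True)
class Peak:
    """A single Lorentzian resonance.

    Parameters
    ----------
    center : float
        Chemical shift of the peak maximum, in ppm.
    width : float
        Half-width at half-maximum, in ppm.  Must be positive.
    amplitude : float
        Peak height in arbitrary units.  Must be non-negative.
    """

    center: float
    width: float
    amplitude: float

    def validate(self, axis_range: tuple[float, float] | None = None) -> None:
        if not self.width > 0:
            raise ParameterError(f"Peak.width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ParameterError(
                f"Peak.amplitude must be >= 0, got {self.amplitude}"
            )
        if axis_range is not None:
            lo, hi = axis_range
            if not (lo <= self.center <= hi):
                raise ParameterError(
                    f"Peak.center {self.center} outside axis range {axis_range}"
                )


def _default_peaks() -> tuple[Peak, ...]:
    # Fabricated, documented constants: aliphatic (amino/organic acids),
    # sugar (dominant, carries the class effect) and aromatic resonances.
    return (
        # aliphatic region 0.8-3.1 ppm
        Peak(0.92, 0.012, 18.0),
        Peak(1.18, 0.010, 14.0),
        Peak(1.33, 0.012, 22.0),
        Peak(1.48, 0.015, 12.0),
        Peak(2.05, 0.014, 16.0),
        Peak(2.35, 0.012, 10.0),
        Peak(2.68, 0.012, 9.0),
        Peak(3.05, 0.010, 8.0),
        # sugar region 3.5-5.5 ppm (strongest peaks)
        Peak(3.62, 0.015, 55.0),
        Peak(3.78, 0.018, 70.0),
        Peak(3.92, 0.015, 60.0),
        Peak(4.12, 0.014, 45.0),
        Peak(5.23, 0.012, 40.0),
        Peak(5.41, 0.012, 28.0),
        # aromatic region 6.5-9.0 ppm
        Peak(6.88, 0.012, 4.0),
        Peak(7.52, 0.014, 3.5),
        Peak(8.46, 0.012, 3.0),
    )


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the two-class spectrum simulator.

    ``class_ratio`` multiplies the amplitudes of peaks whose center lies in
    ``sugar_region`` for the *non-authentic* class; values > 1 therefore make
    the geo-authentic sugar signal relatively lower, as observed on TSP-
    referenced yam spectra.  ``intensity_cv`` is the lognormal coefficient of
    variation of each peak amplitude, drawn once per sample per peak.
    ``noise_sd`` is the standard deviation of additive Gaussian noise.
    """

    n_geo: int = 70
    n_non: int = 70
    axis_range: tuple[float, float] = (0.50, 9.50)
    n_points: int = 2048
    peaks: tuple[Peak, ...] = field(default_factory=_default_peaks)
    sugar_region: tuple[float, float] = (3.50, 6.00)
    class_ratio: float = 1.5
    intensity_cv: float = 0.1
    noise_sd: float = 0.7
    seed: int = 101

    def validate(self) -> None:
        if self.n_geo < 1:
            raise ParameterError(f"n_geo must be >= 1, got {self.n_geo}")
        if self.n_non < 1:
            raise ParameterError(f"n_non must be >= 1, got {self.n_non}")
        if self.n_points < 2:
            raise ParameterError(f"n_points must be >= 2, got {self.n_points}")
        lo, hi = self.axis_range
        if not lo < hi:
            raise ParameterError(f"axis_range must have min < max, got {self.axis_range}")
        if not self.class_ratio > 0:
            raise ParameterError(f"class_ratio must be > 0, got {self.class_ratio}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.intensity_cv < 0:
            raise ParameterError(f"intensity_cv must be >= 0, got {self.intensity_cv}")
        if not self.peaks:
            raise ParameterError("peaks must be non-empty")
        for pk in self.peaks:
            pk.validate(self.axis_range)


def default_synth_params() -> SynthParams:
    """Default simulator settings: 70 + 70 samples on a 0.50-9.50 ppm axis,
    17 Lorentzian peaks, sugar region (3.50, 6.00), class ratio 1.5,
    10 % amplitude CV, noise SD equal to 1 % of the largest peak amplitude,
    seed 101."""
    return SynthParams()


@dataclass
class Spectrum:
    """One sample's 1H NMR trace: a ppm axis plus intensities.

    The ppm axis is strictly monotone; the package stores axes descending
    (NMR display convention) but readers accept either orientation.
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ParameterError(
                "ppm and intensity must be 1-D arrays of equal length"
            )
        d = np.diff(self.ppm)
        if len(d) and not (np.all(d > 0) or np.all(d < 0)):
            raise ParameterError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ParameterError("intensity contains non-finite values")

    def __len__(self) -> int:
        return len(self.ppm)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.label == other.label
            and np.array_equal(self.ppm, other.ppm)
            and np.array_equal(self.intensity, other.intensity)
        )


@dataclass
class Dataset:
    """A labeled collection of spectra sharing one ppm axis."""

    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ParameterError("Dataset must contain at least one spectrum")
        ids = [s.sample_id for s in self.spectra]
        if len(set(ids)) != len(ids):
            raise ParameterError("sample_ids must be unique")
        ref = self.spectra[0].ppm
        for s in self.spectra[1:]:
            if not np.array_equal(s.ppm, ref):
                raise ParameterError("all spectra must share one ppm axis")

    def __len__(self) -> int:
        return len(self.spectra)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.spectra == other.spectra

    @property
    def ppm(self) -> np.ndarray:
        return self.spectra[0].ppm

    @property
    def X(self) -> np.ndarray:
        """Intensity matrix, shape (n_samples, n_points)."""
        return np.stack([s.intensity for s in self.spectra])

    @property
    def labels(self) -> list[str | None]:
        return [s.label for s in self.spectra]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.spectra]


def _lorentzian(ppm: np.ndarray, center: float, width: float) -> np.ndarray:
    # unit-height Lorentzian: w^2 / ((x - c)^2 + w^2)
    return width**2 / ((ppm - center) ** 2 + width**2)


def generate_dataset(params: SynthParams) -> Dataset:
    """Simulate ``n_geo + n_non`` spectra under ``params``.

    Each spectrum is a sum of Lorentzian peaks whose amplitudes are jittered
    by a per-sample, per-peak lognormal factor with coefficient of variation
    ``intensity_cv`` (unit mean); for non-authentic samples, peaks centered
    inside ``sugar_region`` are additionally multiplied by ``class_ratio``.
    Gaussian noise of SD ``noise_sd`` is added.  A fixed seed reproduces the
    dataset bit-identically.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.axis_range
    # descending axis: NMR display convention
    ppm = np.linspace(hi, lo, params.n_points)

    centers = np.array([p.center for p in params.peaks])
    widths = np.array([p.width for p in params.peaks])
    amps = np.array([p.amplitude for p in params.peaks])
    s_lo, s_hi = params.sugar_region
    in_sugar = (centers >= s_lo) & (centers <= s_hi)
    shapes = np.stack([_lorentzian(ppm, c, w) for c, w in zip(centers, widths)])

    if params.intensity_cv > 0:
        sigma = float(np.sqrt(np.log1p(params.intensity_cv**2)))
        mu = -0.5 * sigma**2  # unit-mean lognormal
    else:
        sigma = 0.0
        mu = 0.0

    spectra: list[Spectrum] = []
    for label, count, tag in (
        (GEO_AUTHENTIC, params.n_geo, "geo"),
        (NON_AUTHENTIC, params.n_non, "non"),
    ):
        for i in range(count):
            factors = rng.lognormal(mu, sigma, size=len(amps)) if sigma > 0 else np.ones(len(amps))
            eff = amps * factors
            if label == NON_AUTHENTIC:
                eff = np.where(in_sugar, eff * params.class_ratio, eff)
            intensity = eff @ shapes
            if params.noise_sd > 0:
                intensity = intensity + rng.normal(0.0, params.noise_sd, size=params.n_points)
            spectra.append(
                Spectrum(f"{tag}_{i + 1:03d}", ppm.copy(), intensity, label)
            )
    return Dataset(spectra)


def sugar_region_integral(spectrum: Spectrum, region: tuple[float, float] = (3.50, 6.00)) -> float:
    """Trapezoidal integral of intensity over the sugar region (for QC)."""
    lo, hi = region
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    ppm = spectrum.ppm[mask]
    inten = spectrum.intensity[mask]
    if ppm.size and ppm[0] > ppm[-1]:
        ppm, inten = ppm[::-1], inten[::-1]
    return float(np.trapezoid(inten, ppm))


def _labels_path(path: Path) -> Path:
    return path.with_name(path.stem + "_labels.csv")


def write_dataset_csv(dataset: Dataset, path: str | Path) -> None:
    """Write a spectrum matrix CSV plus a labels sidecar.

    Matrix layout: first column ``ppm``, one column per sample named by
    ``sample_id``.  Labels go to ``<stem>_labels.csv`` with columns
    ``sample_id,label``.
    """
    path = Path(path)
    cols = {"ppm": dataset.ppm}
    cols.update({s.sample_id: s.intensity for s in dataset.spectra})
    pd.DataFrame(cols).to_csv(path, index=False)
    lab = pd.DataFrame(
        {"sample_id": dataset.sample_ids, "label": dataset.labels}
    )
    lab.to_csv(_labels_path(path), index=False)


def read_dataset_csv(path: str | Path, labels_path: str | Path | None = None) -> Dataset:
    """Read a matrix CSV (and labels sidecar) written by :func:`write_dataset_csv`.

    Either axis orientation is accepted; ascending axes are flipped to the
    descending convention.  Non-numeric cells raise :class:`FormatError`
    naming the offending row and column.
    """
    path = Path(path)
    if labels_path is None:
        labels_path = _labels_path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise FormatError(f"malformed CSV {path}: {e}") from e
    if "ppm" not in df.columns:
        raise FormatError(f"{path}: first column must be 'ppm'")
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        bad = np.argwhere(num.isna().to_numpy())[0]
        # +2: header line plus 1-based numbering
        raise FormatError(
            f"{path}: non-numeric cell at line {bad[0] + 2}, "
            f"column '{df.columns[bad[1]]}'"
        )
    labels: dict[str, str] = {}
    labels_path = Path(labels_path)
    if labels_path.exists():
        lab = pd.read_csv(labels_path)
        if not {"sample_id", "label"} <= set(lab.columns):
            raise FormatError(
                f"{labels_path}: expected columns sample_id,label"
            )
        labels = dict(zip(lab["sample_id"].astype(str), lab["label"].astype(str)))
    ppm = num["ppm"].to_numpy()
    flip = len(ppm) > 1 and ppm[0] < ppm[-1]
    if flip:
        ppm = ppm[::-1].copy()
    spectra = []
    for col in df.columns:
        if col == "ppm":
            continue
        inten = num[col].to_numpy()
        if flip:
            inten = inten[::-1].copy()
        spectra.append(Spectrum(str(col), ppm.copy(), inten, labels.get(str(col))))
    if not spectra:
        raise FormatError(f"{path}: no sample columns found")
    return Dataset(spectra)


def with_seed(params: SynthParams, seed: int) -> SynthParams:
    """Return a copy of ``params`` with a different seed."""
    return replace(params, seed=seed)
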