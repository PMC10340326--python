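"""Deterministic rasterization of a 1-D spectrum into a grayscale image.

The renderer draws a minimal trace — foreground polyline on a uniform
background, no axes, ticks, text, margins or anti-aliasing — so that texture
features downstream encode the spectrum, not plotting chrome.  Default
canvas is 1156 x 600 px (width x height), black trace on white.

Mapping rules:

* columns run left to right in order of *decreasing* ppm (NMR display
  convention); after solvent-region excision the retained segments are drawn
  contiguously (column position follows point index, not ppm value);
* intensity 0 maps to the bottom row and the intensity ceiling to the top
  row; values outside [0, ceiling] are clipped;
* with more points than columns each column takes the *maximum* intensity in
  its bin (peak-preserving); empty columns are filled by linear
  interpolation;
* consecutive column rows are joined by vertical runs so the trace is
  4-connected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateInputError, FormatError, ParameterError
from .synth import Dataset, Spectrum

PER_SPECTRUM_MAX = "per_spectrum_max"
GLOBAL_MAX = "global_max"


@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters.  ``intensity_ceiling`` selects the scaling rule:
    ``global_max`` (default; one dataset-wide ceiling, so absolute intensity
    differences between samples survive rendering — yam spectra are
    TSP-referenced and the class signal is an absolute sugar-region
    intensity difference) or ``per_spectrum_max`` (each spectrum scaled to
    its own maximum; render invariant to global rescaling of a spectrum)."""

    width: int = 1156
    height: int = 600
    foreground: int = 0
    background: int = 255
    line_thickness: int = 1
    intensity_ceiling: str = GLOBAL_MAX

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ParameterError("width and height must be >= 3")
        if self.foreground == self.background:
            raise ParameterError("foreground must differ from background")
        for name in ("foreground", "background"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ParameterError(f"{name} must be in [0, 255], got {v}")
        if self.line_thickness < 1:
            raise ParameterError("line_thickness must be >= 1")
        if self.intensity_ceiling not in (PER_SPECTRUM_MAX, GLOBAL_MAX):
            raise ParameterError(
                f"intensity_ceiling must be '{PER_SPECTRUM_MAX}' or "
                f"'{GLOBAL_MAX}', got {self.intensity_ceiling!r}"
            )


@dataclass
class SpectrumImage:
    """A rendered spectrum: uint8 pixel grid plus provenance."""

    pixels: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ParameterError("pixels must be a 2-D grid")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ParameterError("pixel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _trace_rows(intensity: np.ndarray, width: int, height: int, ceiling: float) -> np.ndarray:
    """Per-column pixel row of the trace (0 = top)."""
    n = intensity.size
    cols = np.rint(np.arange(n) * (width - 1) / (n - 1)).astype(int)
    col_int = np.full(width, -np.inf)
    np.maximum.at(col_int, cols, intensity)
    filled = np.isfinite(col_int)
    if not filled.all():
        idx = np.arange(width)
        col_int = np.interp(idx, idx[filled], col_int[filled])
    if ceiling <= 0:
        frac = np.zeros(width)
    else:
        frac = np.clip(col_int, 0.0, ceiling) / ceiling
    return np.rint((1.0 - frac) * (height - 1)).astype(int)


def rasterize(
    spectrum: Spectrum,
    spec: RenderSpec = RenderSpec(),
    ceiling: float | None = None,
) -> SpectrumImage:
    """Render one spectrum.  ``ceiling`` overrides the scaling ceiling (used
    by dataset-level rendering in ``global_max`` mode); by default it is the
    spectrum's own maximum intensity."""
    if len(spectrum) < 2:
        raise DegenerateInputError("rasterize needs at least 2 points")
    inten = spectrum.intensity
    if not np.all(np.isfinite(inten)):
        raise ParameterError("intensity contains non-finite values")
    # columns ordered by decreasing ppm
    if spectrum.ppm[0] < spectrum.ppm[-1]:
        inten = inten[::-1]
    if ceiling is None:
        ceiling = float(inten.max())
    rows = _trace_rows(inten, spec.width, spec.height, ceiling)

    img = np.full((spec.height, spec.width), spec.background, dtype=np.uint8)
    fg = spec.foreground
    img[rows[0], 0] = fg
    for c in range(1, spec.width):
        r0, r1 = rows[c - 1], rows[c]
        lo, hi = (r0, r1) if r0 <= r1 else (r1, r0)
        img[lo : hi + 1, c] = fg
    if spec.line_thickness > 1:
        mask = img == fg
        for dt in range(1, spec.line_thickness):
            shifted = np.zeros_like(mask)
            shifted[dt:, :] = mask[:-dt, :]
            img[shifted] = fg
    return SpectrumImage(img, spectrum.sample_id)


def rasterize_dataset(dataset: Dataset, spec: RenderSpec = RenderSpec()) -> list[SpectrumImage]:
    """Render every spectrum; in ``global_max`` mode the ceiling is the
    dataset-wide maximum intensity."""
    ceiling = None
    if spec.intensity_ceiling == GLOBAL_MAX:
        ceiling = float(max(s.intensity.max() for s in dataset.spectra))
    return [rasterize(s, spec, ceiling) for s in dataset.spectra]


def write_png(image: SpectrumImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG (lossless round trip)."""
    Image.fromarray(image.pixels, mode="L").save(Path(path), format="PNG")


def read_png(path: str | Path) -> SpectrumImage:
    """Read a PNG as 8-bit grayscale.  RGB/RGBA inputs are converted with the
    ITU-R BT.601 luma weights (0.299 R + 0.587 G + 0.114 B)."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.format != "PNG":
                raise FormatError(f"{path} is not a PNG (format={im.format})")
            im.load()
            if im.mode != "L":
                im = im.convert("L")
            pixels = np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as e:
        raise FormatError(f"{path} is not a readable image: {e}") from e
    except OSError as e:
        raise FormatError(f"{path} is truncated or corrupt: {e}") from e
    return SpectrumImage(pixels, path.stem)


class SpectrumRasterizer(BaseEstimator, TransformerMixin):
    """Transformer: intensity matrix (n_samples, n_points) -> image stack
    (n_samples, height, width) of uint8 gray levels.

    In ``global_max`` mode the ceiling is learned from the data seen at fit
    time (``ceiling_``) and reused at transform time.
    """

    def __init__(
        self,
        width: int = 1156,
        height: int = 600,
        foreground: int = 0,
        background: int = 255,
        line_thickness: int = 1,
        intensity_ceiling: str = GLOBAL_MAX,
    ):
        self.width = width
        self.height = height
        self.foreground = foreground
        self.background = background
        self.line_thickness = line_thickness
        self.intensity_ceiling = intensity_ceiling

    def _spec(self) -> RenderSpec:
        return RenderSpec(
            width=self.width,
            height=self.height,
            foreground=self.foreground,
            background=self.background,
            line_thickness=self.line_thickness,
            intensity_ceiling=self.intensity_ceiling,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        spec = self._spec()
        if X.ndim != 2 or X.shape[1] < 2:
            raise DegenerateInputError("X must be 2-D with >= 2 columns")
        self.n_features_in_ = X.shape[1]
        self.ceiling_ = float(X.max()) if spec.intensity_ceiling == GLOBAL_MAX else None
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        spec = self._spec()
        out = np.empty((X.shape[0], spec.height, spec.width), dtype=np.uint8)
        for i, row in enumerate(X):
            # rows are already column-ordered; wrap with a descending dummy axis
            s = Spectrum(f"s{i}", np.arange(row.size)[::-1].astype(float), row)
            out[i] = rasterize(s, spec, self.ceiling_).pixels
        return out
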