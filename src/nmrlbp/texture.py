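"""Rotation-invariant uniform local binary patterns (LBP^riu2).

The operator samples ``p`` points on a circle of radius ``r`` around each
pixel, thresholds them against the center gray value g_c with

    s(x) = 1 if x >= 0 else 0        (ties count as 1),

and measures the uniformity U of the resulting circular bit pattern — the
number of 0<->1 transitions around the circle.  Patterns with U <= 2
("uniform") are coded by their count of set bits (0..p); all non-uniform
patterns share the single code p+1.  An image is summarized by the histogram
over the p+2 codes; with the default r=1, p=8 this is a 10-dimensional
feature vector.  The histogram is invariant to image rotation (exactly so
for rotations that map the sampling circle onto itself) and to adding a
constant gray offset.

Note the tie rule makes a *constant* image map to code p (all-ones
pattern), not 0 — some LBP implementations break ties the other way.
Neighbors at non-integer positions are resolved by bilinear interpolation
(nearest-neighbor available for cross-checks); exact integer positions use
the raw pixel value.  Border pixels whose circle leaves the image are
skipped rather than padded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateInputError, ParameterError
from .imaging import SpectrumImage

MODE_BASIC = "basic"
MODE_RIU2 = "riu2"


@dataclass(frozen=True)
class LBPConfig:
    r: float = 1.0
    p: int = 8
    mode: str = MODE_RIU2
    interpolation: str = "bilinear"

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ParameterError(f"r must be > 0, got {self.r}")
        if self.p < 4 or self.p % 2:
            raise ParameterError(f"p must be even and >= 4, got {self.p}")
        if self.mode not in (MODE_BASIC, MODE_RIU2):
            raise ParameterError(f"mode must be 'basic' or 'riu2', got {self.mode!r}")
        if self.interpolation not in ("bilinear", "nearest"):
            raise ParameterError(
                f"interpolation must be 'bilinear' or 'nearest', got {self.interpolation!r}"
            )


@dataclass(frozen=True)
class NeighborPattern:
    """The p thresholded bits s(g_i - g_c), in sampling order."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ParameterError("bits must be 0 or 1")
        if len(self.bits) < 4:
            raise ParameterError("pattern needs >= 4 bits")


@dataclass
class FeatureVector:
    """Histogram over LBP codes; ``normalization`` is 'counts' or 'frequency'."""

    values: np.ndarray
    normalization: str = "frequency"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _offsets(r: float, p: int) -> tuple[np.ndarray, np.ndarray]:
    """(d_row, d_col) of neighbor i at angle 2*pi*i/p from the +column axis,
    counter-clockwise (rows grow downward, hence d_row = -r sin)."""
    angles = 2.0 * np.pi * np.arange(p) / p
    dr = np.round(-r * np.sin(angles), 12)
    dc = np.round(r * np.cos(angles), 12)
    return dr, dc


def _pixels_of(image) -> np.ndarray:
    if isinstance(image, SpectrumImage):
        return image.pixels.astype(float)
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ParameterError("image must be 2-D")
    return arr


def _bilinear_at(img: np.ndarray, rr: float, cc: float) -> float:
    r0, c0 = math.floor(rr), math.floor(cc)
    fr, fc = rr - r0, cc - c0
    if fr == 0.0 and fc == 0.0:
        return float(img[r0, c0])
    if fr == 0.0:
        return float(img[r0, c0] + fc * (img[r0, c0 + 1] - img[r0, c0]))
    if fc == 0.0:
        return float(img[r0, c0] + fr * (img[r0 + 1, c0] - img[r0, c0]))
    # lerp form: exact on locally constant patches (top == bottom == value)
    top = img[r0, c0] + fc * (img[r0, c0 + 1] - img[r0, c0])
    bot = img[r0 + 1, c0] + fc * (img[r0 + 1, c0 + 1] - img[r0 + 1, c0])
    return float(top + fr * (bot - top))


def sample_neighbors(image, row: int, col: int, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """Gray values of the p circular neighbors of (row, col)."""
    img = _pixels_of(image)
    m = math.ceil(config.r)
    H, W = img.shape
    if not (m <= row < H - m and m <= col < W - m):
        raise ParameterError(
            f"center ({row}, {col}) is within {m} px of the border of a {H}x{W} image"
        )
    dr, dc = _offsets(config.r, config.p)
    out = np.empty(config.p)
    for i in range(config.p):
        rr, cc = row + dr[i], col + dc[i]
        if config.interpolation == "nearest":
            out[i] = img[round(rr), round(cc)]
        else:
            out[i] = _bilinear_at(img, rr, cc)
    return out


def threshold_pattern(center: float, neighbors) -> NeighborPattern:
    """bit_i = s(g_i - g_c) with s(x) = 1 iff x >= 0."""
    neighbors = np.asarray(neighbors, dtype=float)
    return NeighborPattern(tuple(int(g >= center) for g in neighbors))


def uniformity(pattern: NeighborPattern) -> int:
    """Number of circular 0<->1 transitions; even, in [0, p]."""
    b = pattern.bits
    u = abs(b[-1] - b[0])
    for i in range(1, len(b)):
        u += abs(b[i] - b[i - 1])
    return u


def riu2_code(pattern: NeighborPattern) -> int:
    """Count of set bits if U <= 2, else p + 1."""
    if uniformity(pattern) <= 2:
        return sum(pattern.bits)
    return len(pattern.bits) + 1


def basic_code(pattern: NeighborPattern) -> int:
    """Plain LBP code: sum of bit_i * 2^i."""
    return sum(b << i for i, b in enumerate(pattern.bits))


def _pattern_from_int(code: int, p: int) -> NeighborPattern:
    return NeighborPattern(tuple((code >> i) & 1 for i in range(p)))


def riu2_mapping_table(p: int) -> np.ndarray:
    """Map every one of the 2^p basic patterns to its riu2 code.

    The codomain has exactly p + 2 distinct values: 0..p for uniform
    patterns, p + 1 for the rest.
    """
    if p < 4:
        raise ParameterError(f"p must be >= 4, got {p}")
    codes = np.arange(2**p, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(p)) & 1
    trans = np.abs(np.diff(bits, axis=1)).sum(axis=1) + np.abs(bits[:, -1] - bits[:, 0])
    ones = bits.sum(axis=1)
    return np.where(trans <= 2, ones, p + 1).astype(np.int64)


def _neighbor_plane(img: np.ndarray, dr: float, dc: float, m: int, interpolation: str) -> np.ndarray:
    """Interpolated gray value of the neighbor at offset (dr, dc) for every
    interior pixel, using the same arithmetic as :func:`_bilinear_at`."""
    H, W = img.shape
    h, w = H - 2 * m, W - 2 * m
    if interpolation == "nearest":
        dr, dc = float(round(dr)), float(round(dc))
    r0, c0 = math.floor(dr), math.floor(dc)
    fr, fc = dr - r0, dc - c0

    def block(i: int, j: int) -> np.ndarray:
        return img[m + r0 + i : m + r0 + i + h, m + c0 + j : m + c0 + j + w]

    if fr == 0.0 and fc == 0.0:
        return block(0, 0)
    if fr == 0.0:
        return block(0, 0) + fc * (block(0, 1) - block(0, 0))
    if fc == 0.0:
        return block(0, 0) + fr * (block(1, 0) - block(0, 0))
    top = block(0, 0) + fc * (block(0, 1) - block(0, 0))
    bot = block(1, 0) + fc * (block(1, 1) - block(1, 0))
    return top + fr * (bot - top)


def lbp_code_map(image, config: LBPConfig = LBPConfig()) -> np.ndarray:
    """LBP code at every interior pixel (border of width ceil(r) skipped)."""
    img = _pixels_of(image)
    m = math.ceil(config.r)
    H, W = img.shape
    if H <= 2 * m or W <= 2 * m:
        raise DegenerateInputError(
            f"image {H}x{W} too small for radius {config.r} (needs > {2 * m} in both dims)"
        )
    center = img[m : H - m, m : W - m]
    dr, dc = _offsets(config.r, config.p)
    bits = np.empty((config.p,) + center.shape, dtype=np.uint8)
    for i in range(config.p):
        plane = _neighbor_plane(img, dr[i], dc[i], m, config.interpolation)
        bits[i] = plane >= center
    if config.mode == MODE_BASIC:
        weights = (1 << np.arange(config.p, dtype=np.int64)).reshape(-1, 1, 1)
        return (bits.astype(np.int64) * weights).sum(axis=0)
    trans = np.abs(np.diff(bits.astype(np.int8), axis=0)).sum(axis=0) + np.abs(
        bits[-1].astype(np.int8) - bits[0].astype(np.int8)
    )
    ones = bits.sum(axis=0, dtype=np.int64)
    return np.where(trans <= 2, ones, config.p + 1)


def lbp_histogram(
    image,
    config: LBPConfig = LBPConfig(),
    normalization: str = "frequency",
) -> FeatureVector:
    """Histogram of LBP codes over all interior pixels.

    Length is p + 2 in riu2 mode and 2^p in basic mode; 'frequency'
    normalization (default) divides by the interior pixel count so vectors
    are comparable across image sizes.
    """
    if normalization not in ("counts", "frequency"):
        raise ParameterError(f"unknown normalization {normalization!r}")
    codes = lbp_code_map(image, config)
    nbins = config.p + 2 if config.mode == MODE_RIU2 else 2**config.p
    hist = np.bincount(codes.ravel(), minlength=nbins).astype(float)
    if normalization == "frequency":
        hist /= codes.size
    return FeatureVector(hist, normalization)


class LBPHistogram(BaseEstimator, TransformerMixin):
    """Transformer: image stack (n_samples, height, width) -> feature matrix
    (n_samples, p + 2) of riu2 code frequencies."""

    def __init__(
        self,
        r: float = 1.0,
        p: int = 8,
        mode: str = MODE_RIU2,
        interpolation: str = "bilinear",
        normalization: str = "frequency",
    ):
        self.r = r
        self.p = p
        self.mode = mode
        self.interpolation = interpolation
        self.normalization = normalization

    def _config(self) -> LBPConfig:
        return LBPConfig(r=self.r, p=self.p, mode=self.mode, interpolation=self.interpolation)

    def fit(self, X, y=None):
        self._config()  # validate
        return self

    def transform(self, X):
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ParameterError("X must be an image stack (n, height, width)")
        cfg = self._config()
        return np.stack(
            [lbp_histogram(img, cfg, self.normalization).values for img in X]
        )


def write_features_csv(path: str | Path, features: np.ndarray, sample_ids, labels=None) -> None:
    """One row per sample: sample_id, label, then the feature columns."""
    features = np.asarray(features, dtype=float)
    df = pd.DataFrame(features, columns=[f"lbp_{i}" for i in range(features.shape[1])])
    df.insert(0, "label", list(labels) if labels is not None else [""] * len(df))
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(Path(path), index=False)


def read_features_csv(path: str | Path):
    """Inverse of :func:`write_features_csv`; returns (features, ids, labels)."""
    df = pd.read_csv(Path(path))
    ids = df["sample_id"].astype(str).tolist()
    labels = df["label"].astype(str).tolist() if "label" in df.columns else None
    feats = df[[c for c in df.columns if c.startswith("lbp_")]].to_numpy(dtype=float)
    return feats, ids, labels
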