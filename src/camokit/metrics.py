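"""Pairwise background-difference metrics.

Three axes of visual difference between two backgrounds are quantified:

* **color** — Euclidean distance between the image-mean CIELAB vectors;
* **pattern** — sum of absolute differences between granularity curves
  (pattern energy, the SD of the isotropically band-filtered L* image, at
  21 wavelengths from 2 to 2048 px in steps of sqrt(2));
* **luminance** — sum of absolute differences between 32-bin luminance
  histograms (L*/100 over 0-100%).

Each metric is standardized as a proportion of its maximum over the
analysis collection, and the three standardized values are combined into a
single multidimensional pattern-space (MDPS) statistic: the Euclidean norm
of the standardized 3-vector, ranging from 0 (identical) to sqrt(3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage import color as skcolor

from .errors import DimensionError, ValidationError
from .images import RasterImage

#: The 21 band-center wavelengths in pixels: 2 * sqrt(2)^k for k = 0..20.
GRANULARITY_SCALES = 2.0 * np.sqrt(2.0) ** np.arange(21)

#: Geometric half-step between adjacent scales; band k spans
#: [scale / BAND_HALF_STEP, scale * BAND_HALF_STEP) in wavelength.
BAND_HALF_STEP = 2.0 ** 0.25

N_LUMINANCE_BINS = 32


@dataclass
class GranularityCurve:
    """Pattern energy (SD of the band-filtered L* image) per scale."""

    scales: np.ndarray
    energy: np.ndarray

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, float)
        self.energy = np.asarray(self.energy, float)
        if self.scales.shape != (21,) or self.energy.shape != (21,):
            raise ValidationError("granularity curves have exactly 21 bands")
        if (self.energy < 0).any():
            raise ValidationError("pattern energies are nonnegative")


@dataclass
class DifferenceVector:
    """Raw and standardized differences for one background pair."""

    pair_id: str
    d_color: float
    d_pattern: float
    d_luminance: float
    s_color: float | None = None
    s_pattern: float | None = None
    s_luminance: float | None = None
    mdps: float | None = None


def _as_pixels(img) -> np.ndarray:
    px = img.pixels if isinstance(img, RasterImage) else np.asarray(img, float)
    if px.ndim != 3 or px.shape[2] != 3:
        raise DimensionError("expected an (H, W, 3) sRGB array")
    if px.size == 0:
        raise ValidationError("image is empty")
    if px.min() < 0.0 or px.max() > 1.0:
        raise ValidationError("sRGB values must lie in [0, 1]")
    return px


def srgb_to_lab(img) -> np.ndarray:
    """Convert sRGB in [0, 1] to CIE 1976 L*a*b* (D65/2 degrees)."""
    return skcolor.rgb2lab(_as_pixels(img))


def color_difference(a, b) -> float:
    """Euclidean distance between the mean L*a*b* vectors of two images."""
    ma = srgb_to_lab(a).reshape(-1, 3).mean(axis=0)
    mb = srgb_to_lab(b).reshape(-1, 3).mean(axis=0)
    return float(np.linalg.norm(ma - mb))


def band_edges(scale: float) -> tuple[float, float]:
    """Wavelength interval [low, high) passed by the band centered on
    ``scale`` (half-open so adjacent bands tile without overlap)."""
    return scale / BAND_HALF_STEP, scale * BAND_HALF_STEP


def _band_mask(shape: tuple[int, int], lo: float, hi: float) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        wavelength = np.where(f > 0, 1.0 / np.where(f > 0, f, 1.0), np.inf)
    return (wavelength >= lo) & (wavelength < hi)


def band_filtered(luminance: np.ndarray, scale: float) -> np.ndarray:
    """The L* image passed through the isotropic Fourier bandpass centered
    on ``scale`` (used mainly for inspection and cross-checking)."""
    lo, hi = band_edges(scale)
    F = np.fft.fft2(luminance)
    return np.real(np.fft.ifft2(F * _band_mask(luminance.shape, lo, hi)))


def granularity_curve(img) -> GranularityCurve:
    """Granularity (pattern-energy) curve of the L* channel.

    Energy in each band is the population SD of the band-filtered image;
    because every band excludes the DC term this equals the Parseval band
    amplitude, which is how it is computed here.  Wavelengths beyond the
    image size retain only their DC-adjacent support and so report energy
    ~0 rather than being skipped, keeping 21 entries always.
    """
    px = _as_pixels(img)
    if min(px.shape[0], px.shape[1]) < 4:
        raise DimensionError("granularity analysis needs images >= 4 px")
    L = skcolor.rgb2lab(px)[..., 0]
    F = np.fft.fft2(L)
    power = np.abs(F) ** 2
    n = L.size
    fy = np.fft.fftfreq(L.shape[0])[:, None]
    fx = np.fft.fftfreq(L.shape[1])[None, :]
    f = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        wavelength = np.where(f > 0, 1.0 / np.where(f > 0, f, 1.0), np.inf)
    energies = np.empty(21)
    for k, scale in enumerate(GRANULARITY_SCALES):
        lo, hi = band_edges(scale)
        mask = (wavelength >= lo) & (wavelength < hi)
        energies[k] = np.sqrt(power[mask].sum()) / n
    return GranularityCurve(scales=GRANULARITY_SCALES.copy(), energy=energies)


def pattern_difference(a, b) -> float:
    """Sum over the 21 bands of |pattern energy A - pattern energy B|."""
    ea = granularity_curve(a).energy
    eb = granularity_curve(b).energy
    return float(np.abs(ea - eb).sum())


def luminance_histogram(img) -> np.ndarray:
    """Proportion of pixels per luminance bin (L*/100, 32 equal bins over
    0-100%; the last bin is right-closed)."""
    L = srgb_to_lab(img)[..., 0] / 100.0
    counts, _ = np.histogram(
        np.clip(L, 0.0, 1.0), bins=N_LUMINANCE_BINS, range=(0.0, 1.0)
    )
    return counts / counts.sum()


def luminance_difference(a, b) -> float:
    """Sum over the 32 bins of |proportion A - proportion B| (in [0, 2])."""
    return float(np.abs(luminance_histogram(a) - luminance_histogram(b)).sum())


def compute_differences(a, b, pair_id: str) -> DifferenceVector:
    """Raw color, pattern and luminance differences for one pair."""
    return DifferenceVector(
        pair_id=pair_id,
        d_color=color_difference(a, b),
        d_pattern=pattern_difference(a, b),
        d_luminance=luminance_difference(a, b),
    )


def standardize_and_mdps(
    vectors: list[DifferenceVector],
) -> list[DifferenceVector]:
    """Standardize each metric as a proportion of its maximum over the
    collection and fill in the MDPS statistic.

    An all-zero metric axis (no pair differs on it) is left at 0.  Returns
    new vectors; the inputs are not modified.
    """
    if not vectors:
        raise ValidationError("cannot standardize an empty collection")
    maxima = {
        "color": max(v.d_color for v in vectors),
        "pattern": max(v.d_pattern for v in vectors),
        "luminance": max(v.d_luminance for v in vectors),
    }
    out = []
    for v in vectors:
        s_c = v.d_color / maxima["color"] if maxima["color"] > 0 else 0.0
        s_p = v.d_pattern / maxima["pattern"] if maxima["pattern"] > 0 else 0.0
        s_l = (
            v.d_luminance / maxima["luminance"]
            if maxima["luminance"] > 0
            else 0.0
        )
        out.append(
            replace(
                v,
                s_color=s_c,
                s_pattern=s_p,
                s_luminance=s_l,
                mdps=float(np.sqrt(s_c**2 + s_p**2 + s_l**2)),
            )
        )
    return out
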