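"""Luminance extraction and background standardization.

Backgrounds are standardized so that every image presented to an observer has
the same overall mean/median luminance and a similar luminance distribution:
the luminance channel is log-transformed, a 10,000-bin histogram of the logged
values is built, and a quadratic mapping is fitted through the bins holding
the 1st, 50th and 99th percentiles against desired anchor values (the median
anchor sits halfway between the low and high anchors).  The mapping is then
applied to every pixel, leaving equal numbers of pixels beyond the low and
high anchors.

A measured LCD gamma curve is included as a calibration utility for
converting 8-bit pixel values to luminance in lux.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LuminanceImage",
    "NormalizationAnchors",
    "DegenerateImageError",
    "to_luminance",
    "normalize_background",
    "monitor_gamma",
    "load_image",
    "save_image",
]


class DegenerateImageError(ValueError):
    """Raised when an image cannot be normalized (e.g. all pixels equal)."""


@dataclass
class LuminanceImage:
    """A 2-D luminance raster with a provenance flag.

    ``state`` is one of ``"raw"`` (linear camera units), ``"logged"`` or
    ``"normalized"`` (dimensionless anchor units after standardization).
    """

    pixels: np.ndarray
    state: str = "raw"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D array, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have positive dimensions")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixel values")
        if self.state not in ("raw", "logged", "normalized"):
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class NormalizationAnchors:
    """Target values for the 1st / 50th / 99th luminance percentiles.

    The median target must sit halfway between the limits, which makes the
    normalized images symmetric about the median with equal pixel mass at
    both extremes.
    """

    p_low_target: float = 0.1
    p_high_target: float = 0.9
    p_med_target: float = field(default=0.5)
    n_bins: int = 10_000
    percentiles: tuple[float, float, float] = (1.0, 50.0, 99.0)

    def __post_init__(self) -> None:
        mid = 0.5 * (self.p_low_target + self.p_high_target)
        if abs(self.p_med_target - mid) > 1e-12:
            raise ValueError(
                "median target must be halfway between the low and high targets"
            )
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not self.p_low_target < self.p_med_target < self.p_high_target:
            raise ValueError("anchor targets must be strictly increasing")


def to_luminance(rgb: np.ndarray) -> LuminanceImage:
    """Reduce a linear RGB image to luminance as the mean of red and green.

    Human luminance vision pools the longwave and mediumwave channels, so the
    blue channel is ignored entirely.  Input must be linear (not
    gamma-encoded), shaped (H, W, 3) or (H, W) for already-grey input.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim == 2:
        return LuminanceImage(rgb, state="raw")
    if rgb.ndim != 3 or rgb.shape[2] < 2:
        raise ValueError(f"expected (H, W, >=2) colour array, got {rgb.shape}")
    lum = 0.5 * (rgb[..., 0] + rgb[..., 1])
    return LuminanceImage(lum, state="raw")


def _quadratic_through(points: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Exact quadratic coefficients (highest power first) through 3 points."""
    v = np.vander(points, 3)
    return np.linalg.solve(v, targets)


def normalize_background(
    img: LuminanceImage, anchors: NormalizationAnchors | None = None
) -> LuminanceImage:
    """Standardize a background image's luminance distribution.

    Log-transforms the pixels, histograms them into ``anchors.n_bins`` bins,
    and fits a quadratic through the bins of the 1st/50th/99th percentiles
    against the anchor targets.  The quadratic, evaluated on each pixel's bin
    index, gives the normalized image.  Output is clipped at a small positive
    floor so the result remains in the valid domain for a further log
    transform (only pixels in the extreme lower tail can clip).
    """
    if anchors is None:
        anchors = NormalizationAnchors()
    px = img.pixels
    if np.any(px <= 0):
        raise ValueError("normalize_background requires strictly positive pixels")
    logged = np.log(px)
    lo, hi = float(logged.min()), float(logged.max())
    if hi - lo <= 0:
        raise DegenerateImageError("image has no luminance variation")
    scale = anchors.n_bins / (hi - lo)
    bins = np.clip((logged - lo) * scale, 0, anchors.n_bins - 1).astype(np.int64)

    pct_vals = np.percentile(logged, anchors.percentiles)
    pct_bins = np.clip((pct_vals - lo) * scale, 0, anchors.n_bins - 1).astype(np.int64)
    if len(set(pct_bins.tolist())) < 3:
        raise DegenerateImageError(
            "percentile bins coincide; luminance distribution too narrow to normalize"
        )
    targets = np.array(
        [anchors.p_low_target, anchors.p_med_target, anchors.p_high_target]
    )
    coeffs = _quadratic_through(pct_bins.astype(np.float64), targets)
    out = np.polyval(coeffs, bins.astype(np.float64))
    floor = anchors.p_low_target / 1000.0
    np.maximum(out, floor, out=out)
    return LuminanceImage(out, state="normalized")


# Measured LCD gamma curve: 8-bit pixel value -> luminance in lux.
_GAMMA_A = 8.362e-4
_GAMMA_OFFSET = 25.41
_GAMMA_EXP = 2.127
_GAMMA_DECAY = 3.840e11


def monitor_gamma(x):
    """Luminance (lux) produced by an 8-bit pixel value on the study monitor.

    Closed form: ``8.362e-4 * (x + 25.41)**2.127 * exp(-(x + 25.41)/3.840e11)``.
    Strictly increasing on [0, 255]; values outside that range raise.
    """
    arr = np.asarray(x, dtype=np.float64)
    if np.any(arr < 0) or np.any(arr > 255):
        raise ValueError("pixel values must lie in [0, 255]")
    shifted = arr + _GAMMA_OFFSET
    out = _GAMMA_A * shifted**_GAMMA_EXP * np.exp(-shifted / _GAMMA_DECAY)
    return float(out) if np.isscalar(x) else out


def load_image(path) -> LuminanceImage:
    """Read a PNG/TIFF image and reduce it to a raw luminance channel."""
    import imageio.v3 as iio

    data = np.asarray(iio.imread(path), dtype=np.float64)
    if data.ndim == 3:
        return to_luminance(data[..., :3])
    return LuminanceImage(data, state="raw")


def save_image(img: LuminanceImage, path) -> None:
    """Write a luminance image as 32-bit float TIFF (no quantization)."""
    import tifffile

    tifffile.imwrite(str(path), img.pixels.astype(np.float32))
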