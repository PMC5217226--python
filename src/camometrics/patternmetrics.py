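"""Fourier bandpass pattern analysis and luminance-based metrics.

Granularity-style pattern analysis splits a region into 13 spatial scale
bands (2 px doubling in sqrt(2) steps up to 128 px) with annular Fourier
bandpass filters and records the pattern *energy* at each band as the
standard deviation of the filtered pixels within the region.  From these
spectra come:

* PatternDiff — sum of absolute energy differences across bands (how similar
  two patterns are in contrast at every scale);
* five descriptive statistics — maximum energy, dominant spatial frequency,
  proportion power, mean energy, energy SD (pattern heterogeneity);
* Euclidean Pattern Distance — Euclidean distance between the descriptives
  after z-scoring each statistic over the analysis batch, so all five carry
  equal weight.

Luminance-based metrics compare luminance distributions directly:
LuminanceDiff (sum of absolute differences between 20-bin unit-mass
histograms, suited to non-normal two-tone prey), mean luminance difference,
and contrast difference (absolute SD difference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_SCALES",
    "EnergySpectrum",
    "PatternDescriptives",
    "LuminanceMetrics",
    "energy_spectrum",
    "pattern_diff",
    "spectrum_descriptives",
    "euclidean_pattern_distance",
    "luminance_metrics",
]

#: 13 band centres: 2 px to 128 px in multiples of sqrt(2).
DEFAULT_SCALES = tuple(2.0 * np.sqrt(2.0) ** k for k in range(13))

_QUARTER = 2.0 ** 0.25  # geometric half-step between neighbouring bands


@dataclass(frozen=True)
class EnergySpectrum:
    scales: tuple
    energies: np.ndarray
    region_label: str = ""

    def __post_init__(self) -> None:
        if len(self.scales) != len(self.energies):
            raise ValueError("scales and energies must have equal length")


def energy_spectrum(
    image: np.ndarray,
    region_mask: np.ndarray,
    scales=DEFAULT_SCALES,
    region_label: str = "",
) -> EnergySpectrum:
    """Bandpass energy spectrum of one region.

    The region's bounding box is cut out, pixels outside the region mask are
    filled with the region mean, an FFT annulus between the geometric
    midpoints to the neighbouring band centres isolates each scale band, and
    the band energy is the SD of the filtered pixels inside the region.
    Regions smaller than the largest band wavelength are computed anyway
    with a warning (the coarse bands are then poorly resolved).
    """
    image = np.asarray(image, dtype=np.float64)
    region_mask = np.asarray(region_mask, dtype=bool)
    if image.shape != region_mask.shape:
        raise ValueError("image and region mask shapes differ")
    if not region_mask.any():
        raise ValueError("empty region")
    ys, xs = np.nonzero(region_mask)
    y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    crop = image[y0:y1, x0:x1].copy()
    sub = region_mask[y0:y1, x0:x1]
    mean = crop[sub].mean()
    crop[~sub] = mean
    h, w = crop.shape
    if min(h, w) < max(scales):
        warnings.warn(
            f"region extent {h}x{w} below the largest band ({max(scales):.0f} px); "
            "coarse bands are poorly resolved",
            stacklevel=2,
        )
    spec = np.fft.fft2(crop - mean)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    energies = np.empty(len(scales))
    for i, c in enumerate(scales):
        lo_wl, hi_wl = c / _QUARTER, c * _QUARTER  # wavelength band
        band = (f > 1.0 / hi_wl) & (f <= 1.0 / lo_wl)
        filtered = np.real(np.fft.ifft2(np.where(band, spec, 0)))
        energies[i] = filtered[sub].std()
    return EnergySpectrum(tuple(scales), energies, region_label)


def pattern_diff(a: EnergySpectrum, b: EnergySpectrum) -> float:
    """Sum of absolute differences between two energy spectra, band by band."""
    if tuple(a.scales) != tuple(b.scales):
        raise ValueError("spectra use different scale schedules")
    return float(np.abs(a.energies - b.energies).sum())


@dataclass(frozen=True)
class PatternDescriptives:
    max_energy: float
    dominant_scale: float  # band (px) with the maximum energy
    proportion_power: float  # max energy / total energy
    mean_energy: float
    energy_sd: float

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.max_energy,
                self.dominant_scale,
                self.proportion_power,
                self.mean_energy,
                self.energy_sd,
            ]
        )


def spectrum_descriptives(s: EnergySpectrum) -> PatternDescriptives:
    """The five descriptive pattern statistics of one spectrum.

    An all-zero spectrum has no dominant scale; it is reported as NaN (a
    missing value) along with proportion power.
    """
    e = np.asarray(s.energies, dtype=np.float64)
    total = e.sum()
    if total <= 0:
        return PatternDescriptives(0.0, np.nan, np.nan, 0.0, float(e.std()))
    k = int(np.argmax(e))
    return PatternDescriptives(
        max_energy=float(e.max()),
        dominant_scale=float(s.scales[k]),
        proportion_power=float(e.max() / total),
        mean_energy=float(e.mean()),
        energy_sd=float(e.std()),
    )


def euclidean_pattern_distance(
    prey_desc: PatternDescriptives,
    region_desc: PatternDescriptives,
    population: list[PatternDescriptives],
) -> float:
    """Euclidean distance between z-scored descriptive statistics.

    Each of the five statistics is standardized (mean 0, SD 1) over the
    analysis population so all carry equal weight; statistics with zero
    variance in the population are dropped with a warning.
    """
    if len(population) < 2:
        raise ValueError("population must have at least 2 members")
    pop = np.array([p.as_vector() for p in population])
    mu = pop.mean(axis=0)
    sd = pop.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            "dropping zero-variance pattern statistics from the distance",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("all statistics have zero variance in the population")
    za = (prey_desc.as_vector()[keep] - mu[keep]) / sd[keep]
    zb = (region_desc.as_vector()[keep] - mu[keep]) / sd[keep]
    return float(np.linalg.norm(za - zb))


@dataclass(frozen=True)
class LuminanceMetrics:
    luminance_diff: float  # sum |histogram differences|, unit-mass bins
    mean_lum_diff: float
    contrast_diff: float
    mean_region_luminance: float


def luminance_metrics(
    prey_pixels: np.ndarray, region_pixels: np.ndarray, n_bins: int = 20
) -> LuminanceMetrics:
    """Luminance-distribution comparisons between prey and a region.

    Histograms are normalized to unit mass before differencing (regions have
    very different areas), with bin edges spanning the pooled luminance range
    uniformly; identical pixel sets give 0, disjoint-support sets give 2.
    """
    prey = np.asarray(prey_pixels, dtype=np.float64).ravel()
    region = np.asarray(region_pixels, dtype=np.float64).ravel()
    if prey.size == 0 or region.size == 0:
        raise ValueError("empty pixel set")
    lo = min(prey.min(), region.min())
    hi = max(prey.max(), region.max())
    if hi == lo:
        hi = lo + 1.0  # all mass in one shared bin; histogram diff is 0
    edges = np.linspace(lo, hi, n_bins + 1)
    hp, _ = np.histogram(prey, bins=edges)
    hr, _ = np.histogram(region, bins=edges)
    diff = float(np.abs(hp / prey.size - hr / region.size).sum())
    return LuminanceMetrics(
        luminance_diff=diff,
        mean_lum_diff=float(abs(prey.mean() - region.mean())),
        contrast_diff=float(abs(prey.std() - region.std())),
        mean_region_luminance=float(region.mean()),
    )
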