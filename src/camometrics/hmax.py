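"""HMAX-style C1 pattern matching.

A biologically inspired pattern comparison modelled on the ventral-stream
hierarchy: S1 units are absolute responses of even Gabor filters at 4
orientations and 10 scales (sigma 2..20 in steps of 2, same kernels as
GabRat); C1 units pool S1 by taking maxima over local position (disc of
radius sigma + 4) and over the two scales of each neighbouring-scale band,
giving limited position and scale invariance with 4 x 5 channels.

The prey's channel-wise mean C1 vector serves as a soft template — an
overall pattern match rather than a perfect template match (which would test
masquerade, not background matching).  The template is compared at each
point of a background region; similarity is 1 / (1 + Euclidean distance),
summarised by its mean, best (max) and SD (background heterogeneity).  With
rotation allowed, the orientation axis may circularly shift at each site to
whichever of the four rotations matches best; without, the prey is forced to
meet the background at its fixed angle, which better mirrors a prey that
cannot rotate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .gabrat import ANGLES, GaborKernelSpec, gabor_kernel

__all__ = [
    "DEFAULT_HMAX_SIGMAS",
    "SCALE_BANDS",
    "C1Stack",
    "HmaxMatchSummary",
    "s1_c1",
    "prey_template",
    "template_match",
]

#: S1 filter scales (px): 2..20 in steps of 2.
DEFAULT_HMAX_SIGMAS = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20)

#: Neighbouring-scale pairs pooled into each C1 band (default 10 sigmas).
SCALE_BANDS = ((0, 1), (2, 3), (4, 5), (6, 7), (8, 9))


def _bands_for(sigmas) -> tuple:
    """Consecutive disjoint sigma pairs; 10 default sigmas -> 5 C1 bands."""
    return tuple((i, i + 1) for i in range(0, len(sigmas) - 1, 2))


def _disc_max(arr: np.ndarray, radius: int) -> np.ndarray:
    """Exact max filter over a disc footprint.

    Decomposes the disc into its horizontal chords: a 1-D max filter per row
    offset, then a running max over shifted rows.  O(radius * N) instead of
    O(radius^2 * N), which matters for the sigma-20 pooling radius.
    """
    h = arr.shape[0]
    out = np.full_like(arr, -np.inf)
    for dy in range(-radius, radius + 1):
        half = int(np.floor(np.sqrt(radius**2 - dy**2)))
        row_max = ndimage.maximum_filter1d(arr, 2 * half + 1, axis=1, mode="nearest")
        idx = np.clip(np.arange(h) + dy, 0, h - 1)
        np.maximum(out, row_max[idx], out=out)
    return out


@dataclass
class C1Stack:
    """C1 responses: array shaped (n_orientations, n_bands, H, W)."""

    responses: np.ndarray
    sigmas: tuple = DEFAULT_HMAX_SIGMAS

    @property
    def n_orientations(self) -> int:
        return self.responses.shape[0]

    @property
    def n_bands(self) -> int:
        return self.responses.shape[1]


def _convolve_reflect(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    r = (kernel.shape[0] - 1) // 2
    padded = np.pad(image, r, mode="reflect")
    return fftconvolve(padded, kernel[::-1, ::-1], mode="valid")


def s1_c1(image: np.ndarray, sigmas=DEFAULT_HMAX_SIGMAS) -> C1Stack:
    """Compute the C1 stack of an image.

    S1 = |even Gabor response| per orientation and scale; C1 pools each S1
    map with a max filter over a disc of radius sigma + 4, then takes the
    max over the two scales in each band.
    """
    image = np.asarray(image, dtype=np.float64)
    big = 2 * int(np.floor(3 * max(sigmas))) + 1
    if min(image.shape) < big:
        raise ValueError(
            f"image {image.shape} smaller than the largest kernel ({big} px)"
        )
    bands = _bands_for(sigmas)
    c1 = np.zeros((len(ANGLES), len(bands)) + image.shape)
    for ai, angle in enumerate(ANGLES):
        pooled = []
        for sigma in sigmas:
            k = gabor_kernel(GaborKernelSpec(sigma=sigma, angle=angle))
            s1 = np.abs(_convolve_reflect(image, k))
            pooled.append(_disc_max(s1, int(sigma) + 4))
        for bi, band in enumerate(bands):
            c1[ai, bi] = np.maximum.reduce([pooled[s] for s in band])
    return C1Stack(c1, tuple(sigmas))


def prey_template(c1: C1Stack, mask: np.ndarray) -> np.ndarray:
    """Channel-wise mean C1 vector within the prey mask (4 x 5 values)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != c1.responses.shape[2:]:
        raise ValueError("mask shape does not match the C1 stack")
    if not mask.any():
        raise ValueError("empty mask")
    return c1.responses[:, :, mask].mean(axis=2)


@dataclass(frozen=True)
class HmaxMatchSummary:
    mean_match: float
    best_match: float
    sd_match: float
    rotation_allowed: bool
    n_sites: int


def template_match(
    template: np.ndarray,
    c1_region: C1Stack,
    region_mask: np.ndarray,
    allow_rotation: bool = False,
    stride: int = 2,
) -> HmaxMatchSummary:
    """Compare the prey template to every (strided) site of a region.

    Similarity at a site is 1 / (1 + d) with d the Euclidean distance over
    the 20 C1 channels; with rotation allowed the best of the 4 circular
    orientation shifts is taken at each site.
    """
    template = np.asarray(template, dtype=np.float64)
    if template.shape != c1_region.responses.shape[:2]:
        raise ValueError("template channel layout mismatch")
    region_mask = np.asarray(region_mask, dtype=bool)
    sampled = np.zeros_like(region_mask)
    sampled[::stride, ::stride] = True
    sel = region_mask & sampled
    if not sel.any():
        raise ValueError("empty region")
    vecs = c1_region.responses[:, :, sel]  # (4, n_bands, n_sites)
    n_orient = template.shape[0]
    if allow_rotation:
        dists = np.stack(
            [
                np.linalg.norm(
                    np.roll(template, r, axis=0)[:, :, None] - vecs, axis=(0, 1)
                )
                for r in range(n_orient)
            ]
        ).min(axis=0)
    else:
        dists = np.linalg.norm(template[:, :, None] - vecs, axis=(0, 1))
    sims = 1.0 / (1.0 + dists)
    return HmaxMatchSummary(
        mean_match=float(sims.mean()),
        best_match=float(sims.max()),
        sd_match=float(sims.std()),
        rotation_allowed=allow_rotation,
        n_sites=int(sims.size),
    )
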