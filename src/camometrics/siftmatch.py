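"""SIFT feature correspondences between prey and background regions.

Counts how many local features detected in the prey find a matching feature
in a background region, without any attempt at an overall template match —
a prey sharing many local features with its surroundings is harder to find.
Keypoints come from difference-of-Gaussians extrema and are described by
4 x 4 gradient-orientation histograms with 8 bins; prey descriptors are
matched one-directionally to their nearest region descriptor and kept when
they pass the closest/next-closest distance ratio test (0.96 by default —
deliberately permissive so counts are large enough to be roughly normal).
Both prey and region are presented in their entirety on a white background.

Detection and description are delegated to scikit-image's SIFT; exact
keypoint counts differ between SIFT implementations, so the contract here is
the settings record plus the self-match and ratio-monotonicity properties,
not bit-parity with any particular plugin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import SIFT, match_descriptors

__all__ = ["SiftSettings", "composite_on_white", "sift_correspondences"]


@dataclass(frozen=True)
class SiftSettings:
    initial_blur: float = 1.0
    steps_per_octave: int = 8
    descriptor_size: int = 4
    orientation_bins: int = 8
    ratio_threshold: float = 0.96
    background_fill: float = 1.0  # "white" in normalized luminance units

    def __post_init__(self) -> None:
        if not 0 < self.ratio_threshold < 1:
            raise ValueError("ratio_threshold must be in (0, 1)")

    def detector(self) -> SIFT:
        return SIFT(
            sigma_min=self.initial_blur,
            n_scales=self.steps_per_octave,
            n_hist=self.descriptor_size,
            n_ori=self.orientation_bins,
        )


def composite_on_white(
    image: np.ndarray, mask: np.ndarray, fill: float = 1.0
) -> np.ndarray:
    """Keep image pixels inside the mask; fill everything else with white."""
    out = np.full(image.shape, fill, dtype=np.float64)
    out[mask] = image[mask]
    return out


def _descriptors(image: np.ndarray, settings: SiftSettings):
    det = settings.detector()
    try:
        det.detect_and_extract(np.ascontiguousarray(image, dtype=np.float64))
    except RuntimeError:  # skimage raises when no keypoints survive
        return None
    return det.descriptors


def sift_correspondences(
    prey_image: np.ndarray,
    region_image: np.ndarray,
    settings: SiftSettings | None = None,
) -> int:
    """Number of prey features with a ratio-test-passing match in the region.

    Inputs are the white-composited prey and region images.  Zero features in
    either image yields a count of 0 with a warning.
    """
    if settings is None:
        settings = SiftSettings()
    d_prey = _descriptors(prey_image, settings)
    d_region = _descriptors(region_image, settings)
    if d_prey is None or d_region is None or len(d_prey) == 0 or len(d_region) == 0:
        warnings.warn("no SIFT features detected; correspondence count is 0",
                      stacklevel=2)
        return 0
    matches = match_descriptors(
        d_prey, d_region, max_ratio=settings.ratio_threshold, cross_check=False
    )
    return int(len(matches))
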