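"""Artificial two-tone prey generation.

Each prey is a filled triangle (126 x 64 px by default, apex up) cut from a
random patch of its own background, thresholded into a 60% background-tone /
40% pattern split, and recoloured with two tones drawn from background
luminance percentiles.  Two treatments are produced by the same machinery:

* ``disruptive`` — the raw patch is thresholded, so high-contrast pattern
  blobs freely intersect the prey outline, creating false edges;
* ``background_matching`` — a Gaussian gradient first pulls patch values near
  the outline toward the patch median, so no pattern can touch the outline
  and no salient internal lines form parallel to it.

Dark-on-light prey take their (pattern, body) tones from the 20th and 70th
background percentiles; light-on-dark from the 80th and 30th.  These pairs
keep the prey's area-weighted mean luminance near the background median
given the 60/40 split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .imnorm import LuminanceImage

__all__ = [
    "GenerationError",
    "PatchRejectedError",
    "GenerationConfig",
    "PreyStimulus",
    "make_triangle_mask",
    "sample_patch",
    "apply_edge_gradient",
    "threshold_for_proportion",
    "colorize_prey",
    "generate_prey",
    "place_prey",
]

TREATMENTS = ("background_matching", "disruptive")
POLARITIES = ("dark_on_light", "light_on_dark")


class GenerationError(RuntimeError):
    """Prey generation failed (e.g. retries exhausted)."""


class PatchRejectedError(GenerationError):
    """No threshold of this patch attains the target proportion; re-sample."""


@dataclass(frozen=True)
class GenerationConfig:
    """Tunable constants of the prey generator.

    target_pattern_fraction/tolerance define the 60/40 split with its 1%
    acceptance window; percentiles maps polarity to the (pattern, body)
    background percentiles; edge_gradient_sigma is the width (px) of the
    outline suppression used for background-matching prey.
    """

    target_pattern_fraction: float = 0.40
    tolerance: float = 0.01
    edge_gradient_sigma: float = 6.0
    percentiles: dict | None = None
    max_retries: int = 100
    prey_width: int = 126
    prey_height: int = 64

    def __post_init__(self) -> None:
        if not 0 < self.target_pattern_fraction < 1:
            raise ValueError("target_pattern_fraction must be in (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.percentiles is None:
            object.__setattr__(
                self,
                "percentiles",
                {"dark_on_light": (20.0, 70.0), "light_on_dark": (80.0, 30.0)},
            )


@dataclass
class PreyStimulus:
    """A generated two-tone prey.

    ``mask`` is the filled triangle; ``pattern`` (within the mask) marks
    pattern-tone pixels; ``tones`` is (pattern_tone, body_tone) in normalized
    luminance units.  ``placement`` is filled in by :func:`place_prey`.
    """

    mask: np.ndarray
    pattern: np.ndarray
    tones: tuple[float, float]
    treatment: str
    polarity: str
    source_patch_origin: tuple[int, int]
    placement: tuple[int, int] | None = None

    @property
    def pixels(self) -> np.ndarray:
        """Two-tone prey raster (pattern/body tones inside mask, 0 outside)."""
        out = np.zeros(self.mask.shape, dtype=np.float64)
        out[self.mask] = self.tones[1]
        out[self.pattern] = self.tones[0]
        return out

    @property
    def pattern_fraction(self) -> float:
        return float(self.pattern.sum()) / float(self.mask.sum())


def make_triangle_mask(width: int = 126, height: int = 64) -> np.ndarray:
    """Filled isoceles triangle, apex at top-centre, base along the bottom.

    Rasterized symmetrically about the vertical midline: row y keeps columns
    whose centres lie within the triangle's half-width at that depth.
    """
    if width < 3 or height < 3:
        raise ValueError("triangle must be at least 3x3")
    y = np.arange(height)[:, None]
    x = np.arange(width)[None, :]
    half_width = (y + 1) / height * (width / 2.0)
    return np.abs(x + 0.5 - width / 2.0) <= half_width


def sample_patch(
    bg: LuminanceImage,
    origin: tuple[int, int] | None = None,
    size: tuple[int, int] = (126, 64),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Cut a (width, height) luminance patch; random origin if none given."""
    w, h = size
    if bg.width < w or bg.height < h:
        raise ValueError("background smaller than requested patch")
    if origin is None:
        if rng is None:
            rng = np.random.default_rng()
        origin = (
            int(rng.integers(0, bg.width - w + 1)),
            int(rng.integers(0, bg.height - h + 1)),
        )
    x, y = origin
    if not (0 <= x <= bg.width - w and 0 <= y <= bg.height - h):
        raise ValueError(f"patch origin {origin} out of bounds")
    return bg.pixels[y : y + h, x : x + w].copy(), origin


def apply_edge_gradient(
    patch: np.ndarray, mask: np.ndarray, sigma: float
) -> np.ndarray:
    """Pull patch values toward the patch median near the mask outline.

    The pull weight is a Gaussian of the Euclidean distance to the outline
    (full suppression on outline pixels, vanishing in the deep interior), so
    a subsequent threshold cannot classify outline-adjacent pixels as
    pattern.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    med = float(np.median(patch[mask]))
    # Inner boundary pixels of the mask have EDT 1; put the outline at d = 0.
    # Zero-pad so pixels beyond the canvas count as outside the prey (the
    # triangle base sits on the patch edge).
    padded = np.pad(mask, 1)
    d = ndimage.distance_transform_edt(padded)[1:-1, 1:-1] - 1.0
    d[_outline(mask)] = 0.0  # diagonal-boundary pixels sit at EDT sqrt(2)
    weight = np.exp(-(d**2) / (2.0 * sigma**2))
    out = patch.astype(np.float64).copy()
    out[mask] = med + (patch[mask] - med) * (1.0 - weight[mask])
    return out


def threshold_for_proportion(
    patch: np.ndarray,
    mask: np.ndarray,
    cfg: GenerationConfig | None = None,
    tail: str = "lower",
) -> tuple[float, np.ndarray]:
    """Split the masked patch into the target pattern proportion.

    The threshold is the exact order statistic putting ``target`` mass in the
    chosen tail (``lower`` for dark patterns, ``upper`` for light).  Heavily
    tied patches for which no threshold lands within the 1% tolerance raise
    :class:`PatchRejectedError`, signalling the caller to re-sample.
    """
    if cfg is None:
        cfg = GenerationConfig()
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    vals = np.sort(patch[mask].astype(np.float64))
    n = vals.size
    if n < 2 or vals[0] == vals[-1]:
        raise PatchRejectedError("patch has no luminance variation inside mask")
    target = cfg.target_pattern_fraction
    k = int(round(target * n))
    k = min(max(k, 1), n - 1)
    # Candidate cuts around the order statistic; ties can push the achieved
    # fraction off target, in which case the patch is rejected.
    best = None
    for kk in (k, k - 1, k + 1):
        if not 1 <= kk <= n - 1:
            continue
        thr = float(vals[kk]) if tail == "lower" else float(vals[n - kk - 1])
        pattern = (
            (patch < thr) & mask if tail == "lower" else (patch > thr) & mask
        )
        frac = pattern.sum() / n
        err = abs(frac - target)
        if best is None or err < best[0]:
            best = (err, thr, pattern)
    err, thr, pattern = best
    if err > cfg.tolerance:
        raise PatchRejectedError(
            f"achieved pattern fraction off target by {err:.3f} (> tolerance)"
        )
    return thr, pattern


def colorize_prey(
    pattern: np.ndarray,
    mask: np.ndarray,
    bg: LuminanceImage,
    polarity: str,
    cfg: GenerationConfig | None = None,
    treatment: str = "disruptive",
    source_patch_origin: tuple[int, int] = (0, 0),
) -> PreyStimulus:
    """Assign the two tones from background luminance percentiles."""
    if cfg is None:
        cfg = GenerationConfig()
    if polarity not in POLARITIES:
        raise ValueError(f"polarity must be one of {POLARITIES}")
    p_pattern, p_body = cfg.percentiles[polarity]
    pattern_tone = float(np.percentile(bg.pixels, p_pattern))
    body_tone = float(np.percentile(bg.pixels, p_body))
    return PreyStimulus(
        mask=mask.copy(),
        pattern=pattern & mask,
        tones=(pattern_tone, body_tone),
        treatment=treatment,
        polarity=polarity,
        source_patch_origin=tuple(source_patch_origin),
    )


def _outline(mask: np.ndarray) -> np.ndarray:
    from .regions import outline_mask

    return outline_mask(mask)


def generate_prey(
    bg: LuminanceImage,
    treatment: str,
    polarity: str,
    cfg: GenerationConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> PreyStimulus:
    """Generate one prey from a background: sample, (suppress edges),
    threshold, colorize.  Rejected patches are re-sampled from a new random
    location up to ``cfg.max_retries`` times."""
    if cfg is None:
        cfg = GenerationConfig()
    if treatment not in TREATMENTS:
        raise ValueError(f"treatment must be one of {TREATMENTS}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mask = make_triangle_mask(cfg.prey_width, cfg.prey_height)
    tail = "lower" if polarity == "dark_on_light" else "upper"
    outline = _outline(mask)
    for _ in range(cfg.max_retries):
        patch, origin = sample_patch(
            bg, size=(cfg.prey_width, cfg.prey_height), rng=rng
        )
        if treatment == "background_matching":
            patch = apply_edge_gradient(patch, mask, cfg.edge_gradient_sigma)
        try:
            _, pattern = threshold_for_proportion(patch, mask, cfg, tail=tail)
        except PatchRejectedError:
            continue
        if treatment == "background_matching" and np.any(pattern & outline):
            continue  # pattern leaked onto the outline; re-sample
        return colorize_prey(
            pattern, mask, bg, polarity, cfg, treatment=treatment,
            source_patch_origin=origin,
        )
    raise GenerationError(f"no acceptable patch after {cfg.max_retries} retries")


def place_prey(
    bg: LuminanceImage,
    prey: PreyStimulus,
    location: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
    margin: int = 126,
) -> tuple[LuminanceImage, PreyStimulus]:
    """Composite the prey onto the background.

    Random placement keeps the prey at least one body length (``margin``)
    from every image edge so the local comparison region is never clipped.
    Returns the composite slide and a copy of the prey with ``placement``
    recorded.
    """
    h, w = prey.mask.shape
    if location is None:
        if rng is None:
            rng = np.random.default_rng()
        x_max, y_max = bg.width - margin - w, bg.height - margin - h
        if x_max < margin or y_max < margin:
            raise ValueError("background too small for margin-respecting placement")
        location = (
            int(rng.integers(margin, x_max + 1)),
            int(rng.integers(margin, y_max + 1)),
        )
    x, y = location
    if not (0 <= x <= bg.width - w and 0 <= y <= bg.height - h):
        raise ValueError(f"placement {location} puts prey out of bounds")
    slide = bg.pixels.copy()
    slide[y : y + h, x : x + w][prey.mask] = prey.pixels[prey.mask]
    placed = replace(prey, placement=(x, y))
    return LuminanceImage(slide, state=bg.state), placed


def full_mask(prey: PreyStimulus, shape: tuple[int, int]) -> np.ndarray:
    """Prey mask embedded at its placement on a canvas of the given shape."""
    if prey.placement is None:
        raise ValueError("prey has not been placed")
    x, y = prey.placement
    h, w = prey.mask.shape
    out = np.zeros(shape, dtype=bool)
    out[y : y + h, x : x + w] = prey.mask
    return out
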