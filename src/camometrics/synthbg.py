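"""Synthetic bark-like background textures.

Natural background photographs (tree bark in the original experiments) are
not redistributable, so tests and demonstrations run on synthetic stand-ins:
spectrally shaped Gaussian noise whose amplitude spectrum falls off as
``frequency**-beta`` (natural images sit near beta = 1), exponentiated to give
a roughly log-normal luminance distribution, with an optional vertical-streak
anisotropy mimicking bark grain.  Every generated background is passed through
the same percentile normalization as a real photograph, so it satisfies the
standardized mean/median/contrast contract that all downstream metrics assume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imnorm import LuminanceImage, NormalizationAnchors, normalize_background

__all__ = ["SynthBackgroundSpec", "generate_bark_background", "background_battery"]


@dataclass(frozen=True)
class SynthBackgroundSpec:
    """Parameters of one synthetic background.

    beta is the power-law exponent of the amplitude spectrum (0 = white
    noise); contrast_scale scales the log-luminance standard deviation;
    anisotropy > 0 concentrates energy into vertical streaks (bark grain).
    A fixed seed gives a bit-reproducible image.
    """

    width: int = 1920
    height: int = 1080
    beta: float = 1.2
    contrast_scale: float = 1.0
    anisotropy: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("background dimensions must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.contrast_scale <= 0:
            raise ValueError("contrast_scale must be positive")


# Log-luminance SD before normalization; moderate so the exp stays well
# conditioned and the percentile mapping is near-linear.
_BASE_LOG_SD = 0.35


def generate_bark_background(
    spec: SynthBackgroundSpec, anchors: NormalizationAnchors | None = None
) -> LuminanceImage:
    """Generate one normalized synthetic background."""
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((spec.height, spec.width))
    spectrum = np.fft.fft2(white)

    fy = np.fft.fftfreq(spec.height)[:, None]
    fx = np.fft.fftfreq(spec.width)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill DC; mean is set by the normalization
    shaping = f ** (-spec.beta)
    if spec.anisotropy > 0:
        # Vertical streaks vary horizontally: boost energy along the fx axis.
        with np.errstate(invalid="ignore"):
            cos2 = np.where(f > 0, (fx / np.where(f == 0, 1, f)) ** 2, 0.0)
        shaping = shaping * (1.0 + spec.anisotropy * cos2)
    shaping[0, 0] = 0.0

    field = np.real(np.fft.ifft2(spectrum * shaping))
    sd = field.std()
    if sd == 0:
        raise ValueError("degenerate noise field")
    log_lum = field * (_BASE_LOG_SD * spec.contrast_scale / sd)
    raw = LuminanceImage(np.exp(log_lum), state="raw")
    return normalize_background(raw, anchors)


def background_battery(
    n_seeds: int = 8,
    betas: tuple[float, ...] = (0.8, 1.2),
    width: int = 1920,
    height: int = 1080,
    base_seed: int = 0,
    anisotropy: float = 0.5,
) -> list[tuple[SynthBackgroundSpec, LuminanceImage]]:
    """Deterministic battery of backgrounds (n_seeds x len(betas)).

    Stands in for a library of natural background photographs when exercising
    the metric bank; the default 8 seeds x 2 betas gives 16 distinct textures.
    """
    out = []
    for beta in betas:
        for i in range(n_seeds):
            spec = SynthBackgroundSpec(
                width=width,
                height=height,
                beta=beta,
                anisotropy=anisotropy,
                seed=base_seed + i,
            )
            out.append((spec, generate_bark_background(spec)))
    return out
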