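"""Shared fixtures: small normalized backgrounds and placed prey.

Backgrounds here are deliberately smaller than the 1920x1080 presentation
format so the unit suite stays fast; the acceptance tests build the
full-size battery themselves.
"""

import numpy as np
import pytest

from camometrics.imnorm import LuminanceImage
from camometrics.stimgen import full_mask, generate_prey, place_prey
from camometrics.synthbg import SynthBackgroundSpec, generate_bark_background


@pytest.fixture(scope="session")
def bark_bg() -> LuminanceImage:
    """One small normalized bark-like background (640x420)."""
    spec = SynthBackgroundSpec(width=640, height=420, beta=1.2, anisotropy=0.5, seed=1)
    return generate_bark_background(spec)


@pytest.fixture(scope="session")
def bark_bg_pair(bark_bg) -> list[LuminanceImage]:
    spec = SynthBackgroundSpec(width=640, height=420, beta=0.8, anisotropy=0.5, seed=2)
    return [bark_bg, generate_bark_background(spec)]


@pytest.fixture(scope="session")
def placed_disruptive(bark_bg):
    """(slide, prey, full-canvas mask) for one disruptive prey."""
    rng = np.random.default_rng(3)
    prey = generate_prey(bark_bg, "disruptive", "dark_on_light", seed=rng)
    slide, placed = place_prey(bark_bg, prey, rng=rng)
    return slide, placed, full_mask(placed, slide.pixels.shape)


@pytest.fixture(scope="session")
def placed_matching(bark_bg):
    """(slide, prey, full-canvas mask) for one background-matching prey."""
    rng = np.random.default_rng(4)
    prey = generate_prey(bark_bg, "background_matching", "dark_on_light", seed=rng)
    slide, placed = place_prey(bark_bg, prey, rng=rng)
    return slide, placed, full_mask(placed, slide.pixels.shape)
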