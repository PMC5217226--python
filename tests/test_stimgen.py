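"""Two-tone prey generation: geometry, thresholding, tones, placement."""

import numpy as np
import pytest

from camometrics.imnorm import LuminanceImage
from camometrics.regions import outline_mask
from camometrics.stimgen import (
    GenerationConfig,
    PatchRejectedError,
    apply_edge_gradient,
    colorize_prey,
    full_mask,
    generate_prey,
    make_triangle_mask,
    place_prey,
    sample_patch,
    threshold_for_proportion,
)


class TestTriangleMask:
    def test_area_near_half_rectangle(self):
        m = make_triangle_mask(126, 64)
        assert abs(int(m.sum()) - 126 * 64 / 2) / (126 * 64 / 2) < 0.02

    def test_mirror_symmetric(self):
        m = make_triangle_mask(126, 64)
        assert np.array_equal(m, m[:, ::-1])

    def test_apex_up_base_down(self):
        m = make_triangle_mask(126, 64)
        assert m[0].sum() < m[-1].sum()
        assert m[-1].all()  # base spans the bottom row

    def test_degenerate_minimum_size(self):
        m = make_triangle_mask(3, 3)
        assert m.any()

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_triangle_mask(2, 5)


class TestSamplePatch:
    def test_slicing_identity(self, bark_bg):
        patch, origin = sample_patch(bark_bg, origin=(0, 0), size=(126, 64))
        np.testing.assert_array_equal(patch, bark_bg.pixels[0:64, 0:126])
        assert origin == (0, 0)

    def test_seeded_determinism(self, bark_bg):
        p1, o1 = sample_patch(bark_bg, rng=np.random.default_rng(9))
        p2, o2 = sample_patch(bark_bg, rng=np.random.default_rng(9))
        assert o1 == o2
        np.testing.assert_array_equal(p1, p2)

    def test_origins_uniform_over_valid_region(self, bark_bg):
        from scipy.stats import chisquare

        rng = np.random.default_rng(10)
        w_max = bark_bg.width - 126
        h_max = bark_bg.height - 64
        counts = np.zeros(4)
        for _ in range(1000):
            _, (x, y) = sample_patch(bark_bg, rng=rng)
            counts[2 * (y > h_max / 2) + (x > w_max / 2)] += 1
        assert chisquare(counts).pvalue > 0.01

    def test_out_of_bounds_rejected(self, bark_bg):
        with pytest.raises(ValueError):
            sample_patch(bark_bg, origin=(bark_bg.width, 0))


class TestEdgeGradient:
    def test_outline_pixels_become_median(self):
        rng = np.random.default_rng(1)
        mask = make_triangle_mask(30, 16)
        patch = rng.uniform(0, 1, mask.shape)
        med = np.median(patch[mask])
        out = apply_edge_gradient(patch, mask, sigma=3.0)
        np.testing.assert_allclose(out[outline_mask(mask)], med)

    def test_deep_interior_unchanged(self):
        rng = np.random.default_rng(2)
        mask = np.ones((41, 41), dtype=bool)
        patch = rng.uniform(0, 1, mask.shape)
        out = apply_edge_gradient(patch, mask, sigma=2.0)
        centre = out[20, 20]
        assert abs(centre - patch[20, 20]) < 1e-6

    def test_threshold_after_gradient_avoids_outline(self):
        mask = make_triangle_mask(126, 64)
        ramp = np.tile(np.linspace(0, 1, 126), (64, 1))
        weighted = apply_edge_gradient(ramp, mask, sigma=6.0)
        _, pattern = threshold_for_proportion(weighted, mask)
        assert not np.any(pattern & outline_mask(mask))


class TestThreshold:
    def test_ramp_hits_target_fraction(self):
        mask = make_triangle_mask(126, 64)
        ramp = np.tile(np.linspace(0, 1, 126), (64, 1))
        _, pattern = threshold_for_proportion(ramp, mask)
        frac = pattern.sum() / mask.sum()
        assert abs(frac - 0.40) <= 0.01

    def test_upper_tail_selects_light_pixels(self):
        mask = make_triangle_mask(126, 64)
        ramp = np.tile(np.linspace(0, 1, 126), (64, 1))
        thr, pattern = threshold_for_proportion(ramp, mask, tail="upper")
        assert ramp[pattern].min() > thr - 1e-12
        assert abs(pattern.sum() / mask.sum() - 0.40) <= 0.01

    def test_binary_tied_patch_rejected(self):
        mask = make_triangle_mask(30, 16)
        patch = np.zeros(mask.shape)
        patch[:, 15:] = 1.0  # ~50/50 two-valued: no 40% cut exists
        with pytest.raises(PatchRejectedError):
            threshold_for_proportion(patch, mask)

    def test_flat_patch_rejected(self):
        mask = make_triangle_mask(30, 16)
        with pytest.raises(PatchRejectedError):
            threshold_for_proportion(np.ones(mask.shape), mask)

    def test_synthetic_patches_all_within_tolerance(self, bark_bg):
        mask = make_triangle_mask(126, 64)
        rng = np.random.default_rng(11)
        fracs = []
        for _ in range(100):
            patch, _ = sample_patch(bark_bg, rng=rng)
            _, pattern = threshold_for_proportion(patch, mask)
            fracs.append(pattern.sum() / mask.sum())
        fracs = np.array(fracs)
        assert np.all((fracs >= 0.39) & (fracs <= 0.41))


class TestColorize:
    def test_uniform_background_degenerate_tones(self):
        mask = make_triangle_mask(30, 16)
        pattern = np.zeros_like(mask)
        bg = LuminanceImage(np.full((100, 100), 0.5), state="normalized")
        prey = colorize_prey(pattern, mask, bg, "dark_on_light")
        assert prey.tones == (0.5, 0.5)

    def test_percentile_tones_dark_on_light(self):
        rng = np.random.default_rng(3)
        bg = LuminanceImage(rng.uniform(0, 1, (300, 300)), state="normalized")
        mask = make_triangle_mask(30, 16)
        prey = colorize_prey(np.zeros_like(mask), mask, bg, "dark_on_light")
        assert prey.tones[0] == pytest.approx(0.20, abs=0.02)  # pattern = dark
        assert prey.tones[1] == pytest.approx(0.70, abs=0.02)  # body = light

    def test_percentile_tones_light_on_dark(self):
        rng = np.random.default_rng(4)
        bg = LuminanceImage(rng.uniform(0, 1, (300, 300)), state="normalized")
        mask = make_triangle_mask(30, 16)
        prey = colorize_prey(np.zeros_like(mask), mask, bg, "light_on_dark")
        assert prey.tones[0] == pytest.approx(0.80, abs=0.02)  # pattern = light
        assert prey.tones[1] == pytest.approx(0.30, abs=0.02)  # body = dark

    def test_two_tone_contract(self, bark_bg):
        prey = generate_prey(bark_bg, "disruptive", "dark_on_light", seed=5)
        vals = np.unique(prey.pixels[prey.mask])
        assert len(vals) == 2


class TestGeneratePrey:
    def test_matching_prey_avoid_outline(self, bark_bg):
        rng = np.random.default_rng(6)
        for _ in range(20):
            prey = generate_prey(bark_bg, "background_matching", "dark_on_light",
                                 seed=rng)
            assert not np.any(prey.pattern & outline_mask(prey.mask))

    def test_disruptive_prey_touch_outline(self, bark_bg):
        rng = np.random.default_rng(7)
        touching = sum(
            np.any(
                generate_prey(bark_bg, "disruptive", "dark_on_light", seed=rng).pattern
                & outline_mask(make_triangle_mask())
            )
            for _ in range(40)
        )
        assert touching >= 38  # >= 95%

    def test_seeded_determinism(self, bark_bg):
        a = generate_prey(bark_bg, "disruptive", "light_on_dark", seed=8)
        b = generate_prey(bark_bg, "disruptive", "light_on_dark", seed=8)
        np.testing.assert_array_equal(a.pattern, b.pattern)
        assert a.tones == b.tones and a.source_patch_origin == b.source_patch_origin

    def test_mean_fraction_tight_over_battery(self, bark_bg_pair):
        rng = np.random.default_rng(9)
        fracs = [
            generate_prey(bg, t, "dark_on_light", seed=rng).pattern_fraction
            for bg in bark_bg_pair
            for t in ("background_matching", "disruptive")
            for _ in range(30)
        ]
        assert np.mean(fracs) == pytest.approx(0.40, abs=0.005)


class TestPlacePrey:
    def test_round_trip_and_support(self, bark_bg):
        rng = np.random.default_rng(12)
        prey = generate_prey(bark_bg, "disruptive", "dark_on_light", seed=rng)
        slide, placed = place_prey(bark_bg, prey, rng=rng)
        mask = full_mask(placed, slide.pixels.shape)
        x, y = placed.placement
        recovered = slide.pixels[y : y + 64, x : x + 126][prey.mask]
        np.testing.assert_array_equal(recovered, prey.pixels[prey.mask])
        changed = slide.pixels != bark_bg.pixels
        assert not np.any(changed & ~mask)

    def test_margin_respected_over_many_draws(self, bark_bg):
        rng = np.random.default_rng(13)
        prey = generate_prey(bark_bg, "disruptive", "dark_on_light", seed=rng)
        for _ in range(1000):
            _, placed = place_prey(bark_bg, prey, rng=rng)
            x, y = placed.placement
            assert x >= 126 and y >= 126
            assert x + 126 <= bark_bg.width - 126
            assert y + 64 <= bark_bg.height - 126

    def test_out_of_bounds_rejected(self, bark_bg):
        prey = generate_prey(bark_bg, "disruptive", "dark_on_light", seed=14)
        with pytest.raises(ValueError):
            place_prey(bark_bg, prey, location=(bark_bg.width - 50, 0))
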