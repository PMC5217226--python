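"""Bandpass spectra, PatternDiff, descriptives, EPD, luminance metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camometrics.patternmetrics import (
    DEFAULT_SCALES,
    EnergySpectrum,
    PatternDescriptives,
    energy_spectrum,
    euclidean_pattern_distance,
    luminance_metrics,
    pattern_diff,
    spectrum_descriptives,
)

energy_vectors = st.lists(
    st.floats(min_value=0, max_value=100, allow_nan=False), min_size=13, max_size=13
)


def spec(e):
    return EnergySpectrum(DEFAULT_SCALES, np.asarray(e, dtype=float))


class TestSchedule:
    def test_thirteen_bands_sqrt2_steps(self):
        s = np.asarray(DEFAULT_SCALES)
        assert len(s) == 13
        assert s[0] == 2.0 and s[-1] == pytest.approx(128.0)
        np.testing.assert_allclose(s[1:] / s[:-1], np.sqrt(2))


class TestEnergySpectrum:
    def test_uniform_region_zero_energy(self):
        img = np.full((200, 200), 0.4)
        s = energy_spectrum(img, np.ones_like(img, dtype=bool))
        np.testing.assert_allclose(s.energies, 0, atol=1e-12)

    def test_grating_peaks_in_matching_band(self):
        yy, xx = np.mgrid[0:256, 0:256].astype(float)
        img = np.cos(2 * np.pi * xx / 16.0)
        s = energy_spectrum(img, np.ones_like(img, dtype=bool))
        assert s.scales[int(np.argmax(s.energies))] == pytest.approx(16.0)

    def test_small_region_warns_but_computes(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1, (40, 40))
        with pytest.warns(UserWarning):
            s = energy_spectrum(img, np.ones_like(img, dtype=bool))
        assert len(s.energies) == 13

    def test_masked_region_ignores_outside(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (160, 160))
        mask = np.zeros_like(img, dtype=bool)
        mask[10:150, 10:150] = True
        wild = img.copy()
        wild[~mask] = 1e6  # outside values must not leak in
        a = energy_spectrum(img, mask)
        b = energy_spectrum(wild, mask)
        np.testing.assert_allclose(a.energies, b.energies)


class TestPatternDiff:
    def test_identity_and_symmetry(self):
        a, b = spec(np.arange(13.0)), spec(np.arange(13.0)[::-1])
        assert pattern_diff(a, a) == 0
        assert pattern_diff(a, b) == pattern_diff(b, a)

    def test_manual_sum_oracle(self):
        a = spec([1, 0, 2, 0, 0, 0, 0, 0, 0, 0, 0, 0, 5])
        b = spec([0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1])
        assert pattern_diff(a, b) == pytest.approx(1 + 1 + 2 + 4)

    def test_schedule_mismatch_rejected(self):
        a = spec(np.ones(13))
        b = EnergySpectrum(tuple(np.arange(1, 14.0)), np.ones(13))
        with pytest.raises(ValueError):
            pattern_diff(a, b)

    @settings(derandomize=True, max_examples=50)
    @given(energy_vectors, energy_vectors, energy_vectors)
    def test_metric_axioms(self, e1, e2, e3):
        a, b, c = spec(e1), spec(e2), spec(e3)
        ab, bc, ac = pattern_diff(a, b), pattern_diff(b, c), pattern_diff(a, c)
        assert ab >= 0
        assert ac <= ab + bc + 1e-9


class TestDescriptives:
    def test_one_hot_concentration(self):
        e = np.zeros(13)
        e[4] = 3.0
        d = spectrum_descriptives(spec(e))
        assert d.proportion_power == 1.0
        assert d.dominant_scale == pytest.approx(DEFAULT_SCALES[4])

    def test_flat_spectrum(self):
        d = spectrum_descriptives(spec(np.full(13, 2.0)))
        assert d.proportion_power == pytest.approx(1 / 13)
        assert d.energy_sd == 0.0

    def test_arithmetic_oracle(self):
        rng = np.random.default_rng(2)
        e = rng.uniform(0.1, 5, 13)
        d = spectrum_descriptives(spec(e))
        assert d.max_energy == pytest.approx(e.max())
        assert d.dominant_scale == pytest.approx(DEFAULT_SCALES[int(e.argmax())])
        assert d.proportion_power == pytest.approx(e.max() / e.sum())
        assert d.mean_energy == pytest.approx(e.mean())
        assert d.energy_sd == pytest.approx(e.std())

    def test_zero_spectrum_missing_dominant(self):
        d = spectrum_descriptives(spec(np.zeros(13)))
        assert np.isnan(d.dominant_scale)


def _desc(*vals):
    return PatternDescriptives(*vals)


class TestEuclideanPatternDistance:
    def test_identity_zero(self):
        a = _desc(1.0, 4.0, 0.3, 0.5, 0.1)
        pop = [a, _desc(2.0, 8.0, 0.6, 1.0, 0.2)]
        assert euclidean_pattern_distance(a, a, pop) == 0.0

    def test_two_point_closed_form(self):
        a = _desc(1.0, 2.0, 0.1, 0.5, 0.05)
        b = _desc(3.0, 6.0, 0.5, 1.5, 0.25)
        # Population of exactly {a, b}: each statistic z-scores to -1/+1, so
        # every axis gap is 2 and the distance is sqrt(5 * 4) = 2*sqrt(5).
        assert euclidean_pattern_distance(a, b, [a, b]) == pytest.approx(
            2 * np.sqrt(5)
        )

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        pop = [_desc(*rng.uniform(0.1, 5, 5)) for _ in range(8)]
        d1 = euclidean_pattern_distance(pop[0], pop[1], pop)

        def rescale(p):
            v = p.as_vector() * np.array([10, 1, 1, 1, 1]) + np.array(
                [3, 0, 0, 0, 0]
            )
            return _desc(*v)

        pop2 = [rescale(p) for p in pop]
        d2 = euclidean_pattern_distance(pop2[0], pop2[1], pop2)
        assert d1 == pytest.approx(d2)

    def test_zero_variance_statistic_dropped(self):
        a = _desc(1.0, 4.0, 0.5, 0.5, 0.1)
        b = _desc(2.0, 4.0, 0.7, 1.0, 0.3)  # dominant_scale constant in pop
        with pytest.warns(UserWarning):
            d = euclidean_pattern_distance(a, b, [a, b])
        assert d == pytest.approx(2 * np.sqrt(4))


class TestLuminanceMetrics:
    def test_identical_sets_zero(self):
        rng = np.random.default_rng(4)
        px = rng.uniform(0, 1, 500)
        m = luminance_metrics(px, px.copy())
        assert m.luminance_diff == 0 and m.mean_lum_diff == 0 and m.contrast_diff == 0

    def test_disjoint_supports_total_variation_two(self):
        a = np.linspace(0.0, 0.2, 300)
        b = np.linspace(0.8, 1.0, 200)
        assert luminance_metrics(a, b).luminance_diff == pytest.approx(2.0)

    def test_hand_computed_oracle(self):
        prey = np.array([0.1, 0.1, 0.3, 0.3, 0.3, 0.5, 0.5, 0.7, 0.9, 0.9])
        region = np.array([0.2, 0.2, 0.4, 0.4, 0.6, 0.6, 0.8, 0.8, 1.0, 0.0])
        m = luminance_metrics(prey, region, n_bins=5)
        edges = np.linspace(0.0, 1.0, 6)
        hp, _ = np.histogram(prey, edges)
        hr, _ = np.histogram(region, edges)
        assert m.luminance_diff == pytest.approx(np.abs(hp / 10 - hr / 10).sum())
        assert m.mean_lum_diff == pytest.approx(abs(prey.mean() - region.mean()))
        assert m.contrast_diff == pytest.approx(abs(prey.std() - region.std()))
        assert m.mean_region_luminance == pytest.approx(region.mean())

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            luminance_metrics(np.array([]), np.array([0.5]))

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40),
        st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=40),
    )
    def test_histogram_distance_bounds(self, a, b):
        m = luminance_metrics(np.array(a), np.array(b))
        assert 0 <= m.luminance_diff <= 2 + 1e-9
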