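"""Fluorescence quantification: filtering, profiles, domains, spacing, stats."""

import numpy as np
import pytest

from ttubule import (
    BoxROI,
    CircleROI,
    DomainROISet,
    IntensityImage,
    LocalisationResult,
    ProfileTrace,
    box_profile,
    domain_means,
    estimate_spacing,
    median_prefilter,
    panel_trace,
    percent_increase,
    perturbation_percent,
    profile_amplitude,
    rank_markers,
    welch_t,
)
from ttubule.errors import InvalidInputError, QuantError


def flat_image(value=5.0, shape=(40, 60), px=0.1):
    return IntensityImage({"ch": np.full(shape, float(value))}, px)


class TestMedianPrefilter:
    def test_constant_image_unchanged(self):
        img = flat_image(7.0)
        out = median_prefilter(img, 1)
        assert np.array_equal(out.channel("ch"), img.channel("ch"))

    def test_hot_pixel_removed(self):
        arr = np.full((20, 20), 10.0)
        arr[10, 10] = 5000.0
        out = median_prefilter(IntensityImage({"ch": arr}, 0.1), 1)
        assert out.channel("ch")[10, 10] == 10.0

    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(0, 100, (15, 15))
        out = median_prefilter(IntensityImage({"ch": arr}, 0.1), 0)
        assert np.array_equal(out.channel("ch"), arr)


class TestProfiles:
    def test_vertical_stripes_reproduced_exactly(self):
        arr = np.tile(np.where(np.arange(20) % 2 == 0, 3.0, 9.0), (10, 1))
        img = IntensityImage({"ch": arr}, 0.1)
        trace = box_profile(img, "ch", BoxROI(0, 0, 20, 10), prefilter_radius=0)
        assert np.allclose(trace.values, arr[0])

    def test_uniform_image_constant_profile(self):
        trace = box_profile(flat_image(4.0), "ch", BoxROI(5, 5, 20, 10))
        assert np.allclose(trace.values, 4.0)

    def test_out_of_bounds_box_raises(self):
        with pytest.raises(QuantError):
            box_profile(flat_image(), "ch", BoxROI(50, 0, 20, 10))

    def test_amplitude_peak_to_trough_and_offset_invariance(self):
        x = np.linspace(0, 6 * np.pi, 200)
        trace = ProfileTrace(100 + 7.5 * np.sin(x), 0.1)
        assert profile_amplitude(trace) == pytest.approx(15.0, rel=1e-3)
        shifted = ProfileTrace(trace.values + 42.0, 0.1)
        assert profile_amplitude(shifted) == pytest.approx(
            profile_amplitude(trace), rel=1e-12
        )

    def test_constant_trace_zero_amplitude(self):
        assert profile_amplitude(ProfileTrace(np.full(50, 3.3), 0.1)) == 0.0


class TestPerturbation:
    def test_identical_boxes_give_100_percent(self):
        rng = np.random.default_rng(1)
        arr = rng.uniform(10, 200, (30, 80))
        img = IntensityImage({"caax": arr}, 0.1)
        box = BoxROI(5, 5, 40, 20)
        res = perturbation_percent(img, "caax", box, box)
        assert res.percent_of_wildtype == 100.0

    def test_global_gain_invariance(self):
        rng = np.random.default_rng(2)
        arr = rng.uniform(10, 200, (30, 80))
        a, b = BoxROI(0, 0, 35, 30), BoxROI(40, 0, 35, 30)
        p1 = perturbation_percent(IntensityImage({"c": arr}, 0.1), "c", a, b)
        p2 = perturbation_percent(IntensityImage({"c": 2 * arr}, 0.1), "c", a, b)
        assert p1.percent_of_wildtype == pytest.approx(p2.percent_of_wildtype, rel=1e-12)

    def test_zero_wildtype_amplitude_raises(self):
        img = flat_image(5.0)
        box = BoxROI(0, 0, 20, 10)
        with pytest.raises(QuantError):
            perturbation_percent(img, "ch", box, box)

    def test_noiseless_scene_recovers_factor(self, noiseless_scene):
        img, truth = noiseless_scene
        res = perturbation_percent(
            img, "caax", truth.box("expressing"), truth.box("wildtype")
        )
        assert res.percent_of_wildtype == pytest.approx(50.0, abs=1e-9)


class TestDomainMeans:
    def test_uniform_image_unit_enrichment(self):
        img = flat_image(6.0, shape=(50, 50))
        rois = DomainROISet(
            tt=[CircleROI(10, 25, 3)], sl=[CircleROI(25, 5, 3)], it=[CircleROI(40, 25, 3)]
        )
        res = domain_means(img, "ch", rois)
        assert res.mean_tt == res.mean_sl == res.mean_it == 6.0
        assert res.enrichment_tt_vs_it == 1.0
        assert not res.eligible_for_test

    def test_circle_inside_stripe_reads_stripe_value(self):
        arr = np.full((40, 40), 2.0)
        arr[:, 15:25] = 11.0
        img = IntensityImage({"ch": arr}, 0.1)
        rois = DomainROISet(
            tt=[CircleROI(20, 20, 3)], sl=[CircleROI(5, 5, 2)], it=[CircleROI(35, 20, 2)]
        )
        res = domain_means(img, "ch", rois, prefilter_radius=0)
        assert res.mean_tt == 11.0
        assert res.mean_it == 2.0

    def test_empty_domain_raises(self):
        img = flat_image()
        rois = DomainROISet(tt=[CircleROI(-100, -100, 1)], sl=[CircleROI(5, 5, 2)], it=[CircleROI(10, 10, 2)])
        with pytest.raises(QuantError):
            domain_means(img, "ch", rois)

    def test_noiseless_scene_exact_enrichment(self, noiseless_scene):
        img, truth = noiseless_scene
        res = domain_means(img, "marker", truth.domain_rois("wildtype"))
        assert res.enrichment_tt_vs_it == pytest.approx(2.0, abs=1e-12)
        assert res.mean_sl / res.mean_it == pytest.approx(1.5, abs=1e-12)

    def test_default_noise_enrichment_within_10pct(self, default_scene):
        img, truth = default_scene
        res = domain_means(img, "marker", truth.domain_rois("wildtype"))
        assert res.enrichment_tt_vs_it == pytest.approx(2.0, rel=0.1)


class TestRanking:
    @staticmethod
    def result(marker, enrichment):
        return LocalisationResult(marker, mean_tt=enrichment, mean_sl=1.0, mean_it=1.0)

    def test_descending_order_and_eligibility(self):
        results = [self.result("a", 2.0), self.result("b", 1.05), self.result("c", 1.2)]
        ranked = rank_markers(results)
        assert [r.marker for r in ranked] == ["a", "c", "b"]
        assert [r.eligible_for_test for r in ranked] == [True, True, False]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_ties_break_alphabetically(self):
        ranked = rank_markers([self.result(m, 1.5) for m in ("z", "m", "a")])
        assert [r.marker for r in ranked] == ["a", "m", "z"]

    def test_welch_p_attached_to_eligible_markers(self):
        results = [self.result("hi", 2.0), self.result("lo", 1.0)]
        samples = {
            "hi": ([5.0, 6.0, 7.0], [1.0, 1.2, 0.9]),
            "lo": ([1.0, 1.1, 1.2], [1.0, 1.1, 1.2]),
        }
        ranked = rank_markers(results, samples)
        assert ranked[0].p_value is not None and ranked[0].p_value < 0.05
        assert ranked[1].p_value is None  # ineligible: below 10% enrichment


class TestSpacing:
    def test_recovers_19px_period(self):
        x = np.arange(190)
        trace = ProfileTrace(50 + 40 * np.cos(2 * np.pi * x / 19.0), 0.1)
        assert estimate_spacing(trace) == pytest.approx(1.9, abs=0.05)

    def test_constant_trace_no_period(self):
        assert estimate_spacing(ProfileTrace(np.full(100, 2.0), 0.1)) is None

    def test_pixel_size_linearity(self):
        x = np.arange(200)
        values = 10 + 5 * np.cos(2 * np.pi * x / 25.0)
        s1 = estimate_spacing(ProfileTrace(values, 0.1))
        s2 = estimate_spacing(ProfileTrace(values, 0.2))
        assert s2 == pytest.approx(2 * s1, rel=1e-12)

    @pytest.mark.parametrize("period", [10, 19, 25])
    def test_noisy_recovery_within_half_pixel(self, period):
        rng = np.random.default_rng(period)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            x = np.arange(8 * period)
            values = 100 + 30 * np.cos(2 * np.pi * x / period) + rng.normal(0, 6.0, x.size)
            est = estimate_spacing(ProfileTrace(values, 1.0))
            if est is not None and abs(est - period) <= 0.5:
                hits += 1
        assert hits >= 0.95 * n_rep

    def test_scene_spacing_matches_truth(self, default_scene):
        img, truth = default_scene
        trace = box_profile(img, "caax", truth.box("wildtype"))
        assert estimate_spacing(trace) == pytest.approx(1.9, abs=0.05)


class TestWelchAndPercent:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0
        assert res["p_two_tailed"] == pytest.approx(1.0)

    def test_spreadsheet_example(self):
        # frozen from the closed form: t = -1, Welch df = 8, p = 0.34659
        res = welch_t([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert res["t"] == pytest.approx(-1.0, rel=1e-12)
        assert res["df"] == pytest.approx(8.0, rel=1e-12)
        assert res["p_two_tailed"] == pytest.approx(0.346594, abs=1e-6)

    def test_swap_symmetry(self):
        a, b = [1.0, 2.0, 4.0], [5.0, 5.5, 7.0, 8.0]
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1["t"] == pytest.approx(-r2["t"], rel=1e-12)
        assert r1["p_two_tailed"] == pytest.approx(r2["p_two_tailed"], rel=1e-12)

    def test_degenerate_samples_raise(self):
        with pytest.raises(InvalidInputError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(InvalidInputError):
            welch_t([2.0, 2.0], [3.0, 3.0])

    @pytest.mark.parametrize(
        "a,b,expected", [(43.5, 22.8, 90.789), (5.0, 5.0, 0.0), (2.0, 1.0, 100.0)]
    )
    def test_percent_increase(self, a, b, expected):
        assert percent_increase(a, b) == pytest.approx(expected, abs=1e-3)

    def test_percent_increase_zero_baseline(self):
        with pytest.raises(InvalidInputError):
            percent_increase(1.0, 0.0)


class TestPanelTrace:
    def test_uniform_image_flat_with_warning(self):
        with pytest.warns(UserWarning):
            tx, ty = panel_trace(flat_image(3.0), "ch")
        assert np.all(tx.values == 0.0) and np.all(ty.values == 0.0)

    @pytest.mark.filterwarnings("ignore:constant channel")
    def test_single_bright_column_peaks_at_one(self):
        arr = np.ones((20, 30))
        arr[:, 12] = 100.0
        tx, _ = panel_trace(IntensityImage({"ch": arr}, 0.1), "ch")
        assert tx.values.argmax() == 12
        assert tx.values.max() == 1.0
        assert tx.values.min() == 0.0

    def test_scene_trace_period_matches_truth(self, default_scene):
        img, truth = default_scene
        tx, _ = panel_trace(img, "caax")
        x0, x1 = truth.wildtype_bounds
        sub = ProfileTrace(tx.values[x0:x1], img.pixel_size)
        assert estimate_spacing(sub) == pytest.approx(1.9, abs=0.05)
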