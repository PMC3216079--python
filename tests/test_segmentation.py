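"""Color-class models, pixel classification and damage percentage."""

import logging

import numpy as np
import pytest

from oracles import brute_force_classify
from myodamage import (
    ColorClassModel,
    LabelMap,
    Region,
    SegmentationConfig,
    SimulationParams,
    StainSegmentation,
    classify_pixels,
    damage_percentage,
    fit_color_class,
    generate_slice_image,
    generate_training_regions,
    segment_slice,
)
from myodamage.segmentation import BLUE, UNCOLORED, YELLOW


def constant_image(w, h, rgb):
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = rgb
    return img


class TestFitColorClass:
    def test_constant_patch_gives_exact_mean_zero_sd(self):
        img = constant_image(20, 20, (200, 180, 40))
        model = fit_color_class(img, [Region(2, 3, 5, 4)], "yellow")
        assert model.mean == (200.0, 180.0, 40.0)
        assert model.sd == (0.0, 0.0, 0.0)
        assert model.n_pixels == 20

    def test_pooling_invariance_over_region_partition(self, rng):
        img = rng.integers(0, 256, size=(30, 30, 3), dtype=np.uint8)
        whole = fit_color_class(img, [Region(4, 6, 8, 6)], "blue")
        split = fit_color_class(
            img, [Region(4, 6, 8, 3), Region(4, 9, 8, 3)], "blue"
        )
        assert np.allclose(whole.mean, split.mean)
        assert np.allclose(whole.sd, split.sd)

    def test_region_order_does_not_matter(self, noisy_fixture):
        rs = generate_training_regions(noisy_fixture, seed=1)
        fwd = fit_color_class(noisy_fixture.image, rs.yellow_regions, "yellow")
        rev = fit_color_class(noisy_fixture.image, rs.yellow_regions[::-1], "yellow")
        assert fwd == rev

    def test_recovers_generating_noise_sd(self, noisy_fixture):
        rs = generate_training_regions(noisy_fixture, seed=2)
        for regions in (rs.yellow_regions, rs.blue_regions):
            model = fit_color_class(noisy_fixture.image, regions, "c")
            # 1000 pooled pixels: the SD estimate should sit well within 25%
            # of the generating per-channel noise SD of 8
            for s in model.sd:
                assert abs(s - 8.0) <= 0.25 * 8.0

    def test_errors(self):
        img = constant_image(10, 10, (1, 2, 3))
        with pytest.raises(ValueError, match="no training regions"):
            fit_color_class(img, [], "yellow")
        with pytest.raises(ValueError, match="outside"):
            fit_color_class(img, [Region(8, 8, 5, 5)], "yellow")


class TestClassifyPixels:
    def test_class_centers_and_background(self):
        yellow = ColorClassModel("yellow", (220.0, 200.0, 60.0), (5.0, 5.0, 5.0))
        blue = ColorClassModel("blue", (50.0, 70.0, 180.0), (5.0, 5.0, 5.0))
        img = constant_image(3, 1, (0, 0, 0))
        img[0, 0] = (220, 200, 60)
        img[0, 1] = (50, 70, 180)
        labels = classify_pixels(img, Region(0, 0, 3, 1), yellow, blue)
        assert labels.labels.tolist() == [[YELLOW, BLUE, UNCOLORED]]

    def test_matches_brute_force_oracle_on_overlapping_models(self, rng):
        # broad, overlapping classes exercise the single-, both- and
        # neither-box branches plus the tie-break
        img = rng.integers(0, 256, size=(30, 40, 3), dtype=np.uint8)
        yellow = ColorClassModel("yellow", (120.0, 120.0, 120.0), (40.0, 40.0, 40.0))
        blue = ColorClassModel("blue", (140.0, 130.0, 110.0), (50.0, 45.0, 40.0))
        bbox = Region(0, 0, 40, 30)
        got = classify_pixels(img, bbox, yellow, blue)
        expected = brute_force_classify(img, bbox, yellow, blue)
        assert np.array_equal(got.labels, expected)
        assert got.n_both > 0

    def test_matches_brute_force_oracle_on_fixture(self, small_params):
        fx = generate_slice_image(small_params(noise_sd=12.0, seed=21))
        rs = generate_training_regions(fx, n_regions=4, region_size=6, seed=22)
        yellow = fit_color_class(fx.image, rs.yellow_regions, "yellow")
        blue = fit_color_class(fx.image, rs.blue_regions, "blue")
        got = classify_pixels(fx.image, fx.bbox, yellow, blue)
        assert np.array_equal(got.labels, brute_force_classify(fx.image, fx.bbox, yellow, blue))

    def test_zero_sd_channel_requires_exact_equality(self):
        yellow = ColorClassModel("yellow", (100.0, 100.0, 100.0), (0.0, 10.0, 10.0))
        blue = ColorClassModel("blue", (0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
        img = constant_image(2, 1, (100, 100, 100))
        img[0, 1] = (101, 100, 100)  # off by one on the zero-SD channel
        labels = classify_pixels(img, Region(0, 0, 2, 1), yellow, blue)
        assert labels.labels.tolist() == [[YELLOW, UNCOLORED]]

    def test_equidistant_both_class_pixel_goes_to_yellow(self, caplog):
        yellow = ColorClassModel("yellow", (90.0, 100.0, 100.0), (20.0, 20.0, 20.0))
        blue = ColorClassModel("blue", (110.0, 100.0, 100.0), (20.0, 20.0, 20.0))
        img = constant_image(1, 1, (100, 100, 100))
        with caplog.at_level(logging.WARNING, logger="myodamage.segmentation"):
            labels = classify_pixels(img, Region(0, 0, 1, 1), yellow, blue)
        assert labels.labels[0, 0] == YELLOW
        assert labels.n_ties == 1
        assert "equidistant" in caplog.text

    def test_k_monotonicity_of_class_membership(self, noisy_fixture):
        rs = generate_training_regions(noisy_fixture, seed=3)
        window = noisy_fixture.image[noisy_fixture.bbox.slices()]
        prev = -1
        for k in (0.5, 1.0, 1.7, 3.0, 6.0):
            model = fit_color_class(noisy_fixture.image, rs.yellow_regions, "yellow", k=k)
            n = int(np.count_nonzero(model.matches(window)))
            assert n >= prev
            prev = n

    def test_mismatched_k_rejected(self):
        yellow = ColorClassModel("yellow", (1.0, 1.0, 1.0), (1.0, 1.0, 1.0), k=1.7)
        blue = ColorClassModel("blue", (2.0, 2.0, 2.0), (1.0, 1.0, 1.0), k=2.0)
        with pytest.raises(ValueError, match="different k"):
            classify_pixels(constant_image(2, 2, (0, 0, 0)), Region(0, 0, 2, 2), yellow, blue)


class TestDamagePercentage:
    def make_labels(self, codes):
        arr = np.asarray(codes, dtype=np.uint8)
        return LabelMap(arr, Region(0, 0, arr.shape[1], arr.shape[0]))

    def test_all_yellow_is_100(self):
        res = damage_percentage(self.make_labels([[YELLOW, YELLOW]]))
        assert res.damage_pct == 100.0

    def test_equal_counts_is_50(self):
        res = damage_percentage(self.make_labels([[YELLOW, BLUE], [BLUE, YELLOW]]))
        assert res.damage_pct == 50.0

    def test_uncolored_excluded_from_denominator_but_reported(self):
        res = damage_percentage(self.make_labels([[YELLOW, BLUE, UNCOLORED, UNCOLORED]]))
        assert res.damage_pct == 50.0
        assert res.n_uncolored == 2

    def test_zero_colored_pixels_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            damage_percentage(self.make_labels([[UNCOLORED, UNCOLORED]]))


class TestSegmentSlice:
    def test_noise_free_fixture_recovered_exactly(self, small_params):
        fx = generate_slice_image(small_params(true_fraction=0.35, noise_sd=0.0, seed=1))
        rs = generate_training_regions(fx, n_regions=4, region_size=5, seed=2)
        res = segment_slice(fx.image, SegmentationConfig(rs.yellow_regions, rs.blue_regions, fx.bbox))
        assert res.damage_pct == pytest.approx(100.0 * fx.true_fraction, abs=1e-12)

    def test_count_conservation(self, noisy_fixture):
        rs = generate_training_regions(noisy_fixture, seed=4)
        res = segment_slice(
            noisy_fixture.image,
            SegmentationConfig(rs.yellow_regions, rs.blue_regions, noisy_fixture.bbox),
        )
        assert res.n_yellow + res.n_blue + res.n_uncolored == noisy_fixture.bbox.area

    def test_label_swap_symmetry_on_noise_free_fixture(self, small_params):
        fx = generate_slice_image(small_params(true_fraction=0.3, noise_sd=0.0))
        rs = generate_training_regions(fx, n_regions=4, region_size=5, seed=6)
        fwd = segment_slice(fx.image, SegmentationConfig(rs.yellow_regions, rs.blue_regions, fx.bbox))
        swapped = segment_slice(fx.image, SegmentationConfig(rs.blue_regions, rs.yellow_regions, fx.bbox))
        assert swapped.damage_pct == pytest.approx(100.0 - fwd.damage_pct, abs=1e-12)

    def test_region_permutation_leaves_result_unchanged(self, noisy_fixture, rng):
        rs = generate_training_regions(noisy_fixture, seed=8)
        cfg = SegmentationConfig(rs.yellow_regions, rs.blue_regions, noisy_fixture.bbox)
        base = segment_slice(noisy_fixture.image, cfg)
        perm = SegmentationConfig(
            list(rng.permutation(rs.yellow_regions)),
            list(rng.permutation(rs.blue_regions)),
            noisy_fixture.bbox,
        )
        assert segment_slice(noisy_fixture.image, perm).to_dict() == base.to_dict()

    def test_stage_errors_are_named(self, noisy_fixture):
        cfg = SegmentationConfig([], [Region(0, 0, 2, 2)], noisy_fixture.bbox)
        with pytest.raises(ValueError, match="color model fitting failed"):
            segment_slice(noisy_fixture.image, cfg)

    def test_results_summary_mentions_key_quantities(self, noisy_fixture):
        rs = generate_training_regions(noisy_fixture, seed=10)
        out = StainSegmentation(
            noisy_fixture.image, rs.yellow_regions, rs.blue_regions, noisy_fixture.bbox
        ).fit()
        text = out.summary()
        assert "damage percentage" in text and "yellow model" in text
        assert f"{out.result.n_yellow}" in text


def test_ground_truth_recovery_under_noise():
    """Mean absolute error over fixtures spanning 0.1–0.9 at noise SD 10 stays small."""
    errors = []
    for i, f in enumerate(np.linspace(0.1, 0.9, 9)):
        fx = generate_slice_image(
            SimulationParams(true_fraction=float(f), noise_sd=10.0, seed=300 + i)
        )
        rs = generate_training_regions(fx, seed=400 + i)
        res = segment_slice(fx.image, SegmentationConfig(rs.yellow_regions, rs.blue_regions, fx.bbox))
        errors.append(abs(res.damage_pct - 100.0 * fx.true_fraction))
    assert np.mean(errors) <= 3.0
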