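"""Collagen fraction and assembly degree against naive per-pixel oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mtq.core import MicrotissueImage, RoiSpec
from mtq.segmetrics import (
    binarize_collagen,
    collagen_assembly_degree,
    collagen_fraction,
    metrics_timecourse,
)
from mtq.synthdata import FiberFieldParams, simulate_fiber_image, simulate_scenario


def naive_fraction(mask):
    """Brute-force double loop: bright / (bright + black)."""
    nc = nb = 0
    for row in mask.tolist():
        for v in row:
            nc, nb = nc + bool(v), nb + (not bool(v))
    return nc / (nc + nb)


def naive_cad(img):
    """Mean gray over pixels with gray >= 1, histogram-free."""
    tot = n = 0
    for row in img.tolist():
        for v in row:
            if v >= 1:
                tot, n = tot + v, n + 1
    return tot / n if n else 0.0


class TestBinarize:
    def test_all_zero_fixed_zero_threshold(self):
        m = binarize_collagen(np.zeros((8, 8), np.uint8), "fixed", 0)
        assert not m.mask.any()

    def test_otsu_separates_bimodal(self):
        img = np.zeros((10, 10), np.uint8)
        img[:, 5:] = 255
        m = binarize_collagen(img, "otsu")
        assert np.array_equal(m.mask, img == 255)

    def test_noiseless_fibers_binarize_to_ground_truth(self):
        fib = simulate_fiber_image(FiberFieldParams(target_coverage=0.2, seed=7))
        intensity = fib.params.fiber_intensity
        m = binarize_collagen(fib.image.shg, "fixed", intensity // 2)
        assert np.array_equal(m.mask, fib.mask)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binarize_collagen(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            binarize_collagen(np.zeros((4, 4)), "fixed", 300)
        with pytest.raises(ValueError):
            binarize_collagen(np.zeros((4, 4)), "fixed")


class TestMetricOracles:
    def test_trivial_fraction_values(self):
        mask = np.zeros((10, 10), bool)
        assert collagen_fraction(mask) == 0.0
        mask.ravel()[:25] = True
        assert collagen_fraction(mask) == 0.25

    def test_uniform_and_half_zero_cad(self):
        assert collagen_assembly_degree(np.full((6, 6), 100, np.uint8)) == 100.0
        img = np.zeros((6, 6), np.uint8)
        img[:3] = 200
        assert collagen_assembly_degree(img) == 200.0
        assert collagen_assembly_degree(np.zeros((6, 6), np.uint8)) == 0.0

    def test_random_images_match_oracles(self, rng):
        for _ in range(25):
            img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
            mask = img > 128
            assert collagen_fraction(mask) == naive_fraction(mask)
            assert collagen_assembly_degree(img) == pytest.approx(
                naive_cad(img), abs=1e-12
            )

    def test_roi_restriction(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        roi = RoiSpec(x_um=8, y_um=16, width_um=20, height_um=12)
        view = img[16:28, 8:28]
        assert collagen_assembly_degree(img, roi, pixel_size_um=1.0) == pytest.approx(
            naive_cad(view)
        )
        mask = img > 100
        assert collagen_fraction(mask, roi, pixel_size_um=1.0) == naive_fraction(
            mask[16:28, 8:28]
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hnp.arrays(np.uint8, (16, 16), elements=st.integers(0, 127)))
    def test_intensity_scaling_property(self, img):
        """Doubling all grays doubles CAD (the zero set is unchanged)."""
        if not (img >= 1).any():
            return
        scaled = (img.astype(int) * 2).astype(np.uint8)
        assert collagen_assembly_degree(scaled) == pytest.approx(
            2 * collagen_assembly_degree(img), abs=1e-9
        )

    def test_fraction_monotone_in_target_coverage(self):
        fracs = []
        for target in (0.05, 0.15, 0.30):
            fib = simulate_fiber_image(
                FiberFieldParams(target_coverage=target, seed=5)
            )
            m = binarize_collagen(fib.image.shg, "otsu")
            fracs.append(collagen_fraction(m))
        assert fracs[0] < fracs[1] < fracs[2]


class TestTimecourse:
    def test_single_roi_matches_direct_ops(self):
        fib = simulate_fiber_image(
            FiberFieldParams(target_coverage=0.2, seed=9, background_noise_sd=3)
        )
        per_roi, summary = metrics_timecourse(
            {"day4": [fib.image]}, n_rois=1, roi_size_um=100.0
        )
        assert len(per_roi) == 1
        row = per_roi.iloc[0]
        roi = RoiSpec(
            x_um=row_roi_origin(fib.image.shg.shape, fib.image.pixel_size_um),
            y_um=row_roi_origin(fib.image.shg.shape, fib.image.pixel_size_um),
        )
        crop = roi.crop(fib.image.shg, fib.image.pixel_size_um)
        assert row["cad"] == pytest.approx(naive_cad(crop))

    def test_degradation_series_fraction_decreases(self):
        scn = simulate_scenario("tumor_like", seed=3, noise_sd=0.0)
        images = {tp.timepoint: [tp.image] for tp in scn.timepoints}
        per_roi, summary = metrics_timecourse(
            images, n_rois=4, roi_size_um=50.0, method="fixed", fixed_threshold=100
        )
        means = summary.set_index("timepoint")["collagen_fraction_mean"]
        assert means["day4"] > means["day8"] > means["day12"]

    def test_identical_rois_give_zero_sem(self):
        tile = np.tile(np.arange(64, dtype=np.uint8), (64, 1))
        img = MicrotissueImage({"shg": np.tile(tile, (2, 2))}, 1.0, label="t")
        per_roi, summary = metrics_timecourse(
            {"d": [img]}, n_rois=4, roi_size_um=64.0
        )
        assert summary.loc[0, "cad_sem"] == pytest.approx(0.0, abs=1e-12)
        assert summary.loc[0, "collagen_fraction_sem"] == pytest.approx(0.0, abs=1e-12)


def row_roi_origin(shape, px):
    """Origin of the single centred 100 um ROI used by the grid layout."""
    side = 100.0 / px
    return (shape[0] - side) / 2 * px
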