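"""Generator ground truth: determinism, angle marginals, coverage control."""

import numpy as np
import pandas as pd
import pytest

from mtq.synthdata import (
    CellFieldParams,
    FiberFieldParams,
    PlateSpec,
    draw_axial_von_mises,
    simulate_cell_image,
    simulate_fiber_image,
    simulate_plate,
    simulate_scenario,
    write_image,
)


def axial_mean_deg(angles_deg):
    """Independent circular-statistics oracle: axial mean via doubled angles."""
    z = np.mean(np.exp(2j * np.deg2rad(angles_deg)))
    return np.rad2deg(np.angle(z)) / 2.0, np.abs(z)


class TestFiberField:
    def test_empty_field_is_all_zero(self):
        fib = simulate_fiber_image(
            FiberFieldParams(n_fibers=0, background_noise_sd=0.0)
        )
        assert fib.image.shg.sum() == 0
        assert not fib.mask.any()
        assert fib.angles_deg.size == 0

    def test_deterministic_for_seed(self):
        p = FiberFieldParams(n_fibers=40, kappa=3.0, seed=7, background_noise_sd=5.0)
        a, b = simulate_fiber_image(p), simulate_fiber_image(p)
        assert np.array_equal(a.image.shg, b.image.shg)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.angles_deg, b.angles_deg)

    def test_isotropic_angles_have_zero_resultant(self):
        angles = draw_axial_von_mises(np.random.default_rng(0), 0.0, 0.0, 10_000)
        _, resultant = axial_mean_deg(angles)
        assert resultant < 0.02
        assert np.all((angles > -90) & (angles <= 90))

    @pytest.mark.parametrize("mean_deg", [-30.0, 0.0, 60.0])
    def test_axial_mean_converges_to_mean_angle(self, mean_deg):
        angles = draw_axial_von_mises(np.random.default_rng(1), mean_deg, 8.0, 10_000)
        mean_hat, _ = axial_mean_deg(angles)
        # compare on the axial circle (distance modulo 180)
        d = abs(mean_hat - mean_deg)
        assert min(d, 180 - d) < 1.0

    @pytest.mark.parametrize("target", [0.05, 0.15, 0.30, 0.50])
    def test_coverage_control(self, target):
        fib = simulate_fiber_image(
            FiberFieldParams(target_coverage=target, seed=11)
        )
        assert abs(fib.coverage - target) <= 0.02

    def test_unreachable_coverage_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            FiberFieldParams(target_coverage=0.96)

    def test_eight_bit_output(self):
        fib = simulate_fiber_image(
            FiberFieldParams(n_fibers=30, background_noise_sd=30.0, seed=2)
        )
        assert fib.image.shg.dtype == np.uint8


class TestCellField:
    def test_exact_count_and_separation(self):
        p = CellFieldParams(n_cells=40, min_separation_px=10.0, seed=3)
        cf = simulate_cell_image(p)
        assert len(cf.centers_px) == 40
        d = np.linalg.norm(
            cf.centers_px[:, None] - cf.centers_px[None, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10.0
        nr, nc = p.image_size_px
        assert np.all((cf.centers_px >= 0) & (cf.centers_px < [nr, nc]))

    def test_zero_cells(self):
        cf = simulate_cell_image(CellFieldParams(n_cells=0))
        assert cf.image.channel("gfp").sum() == 0


class TestScenarios:
    def test_stroma_is_isotropic_tumor_is_aligned(self):
        stroma = simulate_scenario("stroma_like", seed=0)
        assert stroma.kappa == 0.0
        tumor = simulate_scenario("tumor_like", seed=0)
        assert -35.0 <= tumor.mean_angle_deg <= -20.0
        assert tumor.kappa > 0

    def test_same_seed_bit_identical(self):
        a = simulate_scenario("tumor_like", seed=5)
        b = simulate_scenario("tumor_like", seed=5)
        for ta, tb in zip(a.timepoints, b.timepoints):
            assert np.array_equal(ta.image.shg, tb.image.shg)
            assert np.array_equal(ta.image.channel("gfp"), tb.image.channel("gfp"))
            assert np.array_equal(ta.cell_centers_px, tb.cell_centers_px)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            simulate_scenario("necrotic_core", seed=0)

    def test_tumor_degradation_reduces_mask_coverage(self):
        scn = simulate_scenario("tumor_like", seed=1)
        cov = [tp.fiber_mask.mean() for tp in scn.timepoints]
        assert cov[0] > cov[1] > cov[2]


class TestPlate:
    def test_hill_midpoint_and_control(self):
        spec = PlateSpec(cv=0.0, floor_viability=0.0, seed=0)
        od = simulate_plate(spec)
        ctrl = od.loc[od.dose_uM == 0, "od"]
        assert np.allclose(ctrl, spec.od_control_mean)
        mid = od.loc[od.dose_uM == spec.ic50_uM, "od"]
        assert np.allclose(mid, spec.od_control_mean / 2)

    def test_all_ods_positive_and_cv_calibrated(self):
        spec = PlateSpec(cv=0.1, n_replicates=6, seed=9)
        od = simulate_plate(spec)
        assert (od["od"] > 0).all()
        rel = od.groupby(["timepoint", "dose_uM"])["od"].agg(
            lambda s: s.std(ddof=1) / s.mean()
        )
        # replicate CV ~ 0.1 within +-50% at n=6, averaged over conditions
        assert 0.05 < rel.mean() < 0.15

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError, match="cv"):
            PlateSpec(cv=-0.1)


def test_image_roundtrip_with_sidecar(tmp_path):
    fib = simulate_fiber_image(FiberFieldParams(n_fibers=10, seed=0))
    out = tmp_path / "field.tif"
    write_image(fib.image, out, {"angles_deg": fib.angles_deg})
    import json

    import tifffile

    arr = tifffile.imread(out)
    assert np.array_equal(arr.squeeze(), fib.image.shg)
    side = json.loads(out.with_suffix(".json").read_text())
    assert np.allclose(side["angles_deg"], fib.angles_deg)
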