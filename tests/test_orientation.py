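"""Structure-tensor field against closed-form gratings and an eigen oracle."""

import numpy as np
import pytest

from mtq.core import RoiSpec, fold_axial_deg
from mtq.orientation import (
    angle_histogram,
    coherency_index,
    orientation_color_map,
    orientation_histogram,
    structure_tensor_field,
)
from mtq.synthdata import FiberFieldParams, simulate_fiber_image


def grating(theta_deg, size=128, period=8.0):
    """Sinusoidal grating with stripes running along theta (math convention)."""
    th = np.deg2rad(theta_deg)
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    x, y = cc, -rr
    phase = (-x * np.sin(th) + y * np.cos(th)) * 2 * np.pi / period
    return 127.5 + 127.5 * np.cos(phase)


def axial_diff_deg(a, b):
    d = np.abs(np.asarray(a) - np.asarray(b)) % 180.0
    return np.minimum(d, 180.0 - d)


def eigen_oracle(img, sigma_g=1.0, sigma_w=1.0):
    """Independent per-pixel 2x2 eigendecomposition of the structure tensor."""
    from scipy import ndimage

    img = np.asarray(img, float)
    fx = ndimage.gaussian_filter(img, sigma_g, order=(0, 1), mode="reflect")
    fy = -ndimage.gaussian_filter(img, sigma_g, order=(1, 0), mode="reflect")
    win = lambda a: ndimage.gaussian_filter(a, sigma_w, mode="reflect")
    jxx, jyy, jxy = win(fx * fx), win(fy * fy), win(fx * fy)
    J = np.moveaxis(
        np.array([[jxx, jxy], [jxy, jyy]]), (0, 1), (-2, -1)
    )  # (H, W, 2, 2)
    evals, evecs = np.linalg.eigh(J)  # ascending eigenvalues
    # fiber orientation = eigenvector of the SMALLEST eigenvalue, (vx, vy)
    # with vy in math orientation = -row component... here J is expressed in
    # (x, y) gradient coordinates already, so the eigenvector is (vx, vy)
    v = evecs[..., :, 0]
    theta = fold_axial_deg(np.degrees(np.arctan2(v[..., 1], v[..., 0])))
    lam1, lam2 = evals[..., 1], evals[..., 0]  # lam1 >= lam2
    energy = lam1 + lam2
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(energy > 0, (lam1 - lam2) / energy, 0.0)
    return theta, energy, coh


class TestStructureTensor:
    def test_constant_image_has_zero_energy_and_coherency(self):
        fld = structure_tensor_field(np.full((32, 32), 7.0))
        assert np.allclose(fld.energy, 0.0)
        assert np.allclose(fld.coherency, 0.0)
        assert np.allclose(fld.theta_deg, 0.0)

    @pytest.mark.parametrize("theta0", [-60.0, -30.0, 0.0, 30.0, 60.0])
    def test_grating_orientation_recovered(self, theta0):
        fld = structure_tensor_field(grating(theta0))
        inner = np.s_[16:-16, 16:-16]
        med = np.median(fld.theta_deg[inner])
        assert axial_diff_deg(med, theta0) <= 2.0
        assert np.median(fld.coherency[inner]) >= 0.95

    def test_matches_eigen_oracle(self, rng):
        img = rng.integers(0, 256, (48, 48)).astype(float)
        fld = structure_tensor_field(img)
        theta_o, energy_o, coh_o = eigen_oracle(img)
        assert np.allclose(fld.energy, energy_o, atol=1e-9)
        assert np.allclose(fld.coherency, coh_o, atol=1e-6)
        ok = coh_o > 1e-4  # orientation is ill-defined at isotropic pixels
        assert np.max(axial_diff_deg(fld.theta_deg[ok], theta_o[ok])) < 1e-6

    def test_coherency_bounds_on_random_images(self, rng):
        img = rng.normal(128, 40, (100, 100))
        fld = structure_tensor_field(img)
        assert fld.coherency.min() >= 0.0
        assert fld.coherency.max() <= 1.0

    def test_rotation_equivariance(self):
        from scipy import ndimage as ndi

        base = grating(10.0, size=160)
        fld0 = structure_tensor_field(base)
        # scipy rotates in (row, col) with angle CCW in array coords, which is
        # CW in math orientation; the recovered angle shifts by -angle
        rot = ndi.rotate(base, 15.0, reshape=False, mode="reflect")
        fld1 = structure_tensor_field(rot)
        inner = np.s_[40:-40, 40:-40]
        shift = axial_diff_deg(
            np.median(fld1.theta_deg[inner]), np.median(fld0.theta_deg[inner])
        )
        assert abs(shift - 15.0) <= 2.0


class TestCoherencyIndex:
    def test_grating_index_near_one(self):
        fld = structure_tensor_field(grating(-30.0))
        assert coherency_index(fld) >= 0.95

    def test_all_masked_roi_returns_zero(self):
        fld = structure_tensor_field(np.full((64, 64), 3.0))
        assert coherency_index(fld) == 0.0

    def test_empty_roi_rejected(self):
        fld = structure_tensor_field(grating(0.0, size=64))
        with pytest.raises(ValueError):
            coherency_index(fld, RoiSpec(500.0, 500.0, 10, 10), pixel_size_um=1.0)

    def test_monotone_in_kappa(self):
        means = []
        for kappa in (0.0, 2.0, 8.0, 32.0):
            vals = []
            for seed in range(5):
                fib = simulate_fiber_image(
                    FiberFieldParams(
                        mean_angle_deg=-30.0,
                        kappa=kappa,
                        target_coverage=0.15,
                        background_noise_sd=4.0,
                        seed=300 + seed,
                    )
                )
                fld = structure_tensor_field(fib.image.shg, sigma_window_px=4.0)
                vals.append(coherency_index(fld))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2] < means[3]


class TestHistogram:
    def test_modal_bin_recovers_von_mises_mean(self, aligned_fiber_field):
        fld = structure_tensor_field(aligned_fiber_field.image.shg)
        hist = orientation_histogram(fld)
        assert axial_diff_deg(hist.modal_angle_deg, -30.0) <= 5.0

    def test_uniform_angles_have_flat_histogram(self):
        angles = np.random.default_rng(8).uniform(-90, 90, 10_000)
        hist = angle_histogram(angles)
        assert hist.counts.max() <= 3 * np.median(hist.counts)

    def test_minmax_normalization_of_counts(self):
        hist = angle_histogram(np.array([-80.0, -80.0, 0.0, 0.0, 0.0, 50.0]), 60.0)
        assert np.allclose(sorted(hist.normalized_counts), [0.0, 0.5, 1.0])

    def test_empty_mask_rejected(self):
        fld = structure_tensor_field(grating(0.0, size=64))
        with pytest.raises(ValueError):
            orientation_histogram(fld, mask=np.zeros((64, 64), bool))


class TestColorMap:
    def test_constant_image_renders_gray(self):
        fld = structure_tensor_field(np.full((32, 32), 9.0))
        rgb = orientation_color_map(fld)
        assert rgb.shape == (32, 32, 3)
        assert np.all(rgb[..., 0] == rgb[..., 1])  # zero saturation -> gray

    def test_grating_has_single_dominant_hue(self):
        import matplotlib.colors as mcolors

        shg = grating(-30.0)
        fld = structure_tensor_field(shg)
        rgb = orientation_color_map(fld, brightness=shg)
        hsv = mcolors.rgb_to_hsv(rgb[16:-16, 16:-16] / 255.0)
        bright = hsv[..., 2] > 0.5
        assert np.std(hsv[..., 0][bright]) < 0.05

    def test_two_half_images_two_hues(self):
        import matplotlib.colors as mcolors

        img = np.concatenate(
            [grating(-60.0, size=96)[:, :48], grating(60.0, size=96)[:, 48:]], axis=1
        )
        fld = structure_tensor_field(img)
        rgb = orientation_color_map(fld, brightness=img)
        hsv = mcolors.rgb_to_hsv(rgb / 255.0)
        left = np.median(hsv[16:-16, 8:40, 0])
        right = np.median(hsv[16:-16, 56:88, 0])
        assert abs(left - right) > 0.2
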