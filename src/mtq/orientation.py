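"""Structure-tensor orientation analysis of fibrous images.

For every pixel the local structure tensor

    J = G_sigma_w * [ fx^2   fx fy ]
                    [ fx fy  fy^2  ]

is formed from Gaussian-derivative gradients (fx along image x/columns, fy
along mathematical y, i.e. the negated row derivative) smoothed by a Gaussian
window of width ``sigma_window_px``. Its eigen-structure yields:

* orientation theta: the direction of the smallest-eigenvalue eigenvector
  (fibers are perpendicular to the dominant gradient), in degrees in
  (-90, 90] following the package angle convention;
* energy: the tensor trace Jxx + Jyy;
* coherency: the normalized eigenvalue anisotropy
  sqrt((Jxx - Jyy)^2 + 4 Jxy^2) / (Jxx + Jyy), in [0, 1] — 1 for perfectly
  aligned structure, 0 for isotropic texture (and, by convention, wherever
  the energy vanishes).

ROI summaries mirror common practice for fiber-alignment readouts: a
coherency index (mean per-pixel coherency over sufficiently energetic
pixels, defaults: energy >= 2% of the ROI maximum, coherency cutoff 20% for
distribution masks) and a min-max-normalized orientation histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.colors import hsv_to_rgb
from scipy import ndimage

from .core import RoiSpec, fold_axial_deg

__all__ = [
    "OrientationField",
    "OrientationHistogram",
    "structure_tensor_field",
    "coherency_index",
    "orientation_histogram",
    "angle_histogram",
    "orientation_color_map",
]

MIN_ENERGY_FRAC = 0.02  # energy cutoff as a fraction of the ROI maximum
MIN_COHERENCY = 0.20  # coherency cutoff for distribution masks


@dataclass
class OrientationField:
    """Per-pixel orientation angle, energy and coherency."""

    theta_deg: np.ndarray
    energy: np.ndarray
    coherency: np.ndarray
    sigma_gradient_px: float
    sigma_window_px: float

    @property
    def border_px(self) -> int:
        """Width of the boundary band affected by convolution padding."""
        return int(np.ceil(3 * max(self.sigma_gradient_px, self.sigma_window_px)))

    def interior_mask(self) -> np.ndarray:
        m = np.zeros(self.theta_deg.shape, dtype=bool)
        b = self.border_px
        if 2 * b < min(m.shape):
            m[b:-b, b:-b] = True
        return m

    def analysis_mask(
        self,
        min_energy_frac: float = MIN_ENERGY_FRAC,
        min_coherency: float = MIN_COHERENCY,
        exclude_border: bool = True,
    ) -> np.ndarray:
        """Default pixel-selection mask: energetic, coherent, interior."""
        sel = self.interior_mask() if exclude_border else np.ones_like(self.coherency, bool)
        emax = self.energy[sel].max() if sel.any() else 0.0
        if emax > 0:
            sel &= self.energy >= min_energy_frac * emax
        sel &= self.coherency >= min_coherency
        return sel


@dataclass
class OrientationHistogram:
    bin_centers_deg: np.ndarray
    counts: np.ndarray
    normalized_counts: np.ndarray
    mask_description: str = ""

    @property
    def modal_angle_deg(self) -> float:
        return float(self.bin_centers_deg[int(np.argmax(self.counts))])


def structure_tensor_field(
    img: np.ndarray,
    sigma_gradient_px: float = 1.0,
    sigma_window_px: float = 1.0,
) -> OrientationField:
    """Compute the per-pixel structure tensor eigen-summary of a 2D image.

    Convolutions use reflective boundary handling; a border band of width
    3 sigma is flagged by :meth:`OrientationField.interior_mask` and should
    be excluded from ROI statistics. A constant image yields zero energy and
    zero coherency everywhere (orientation set to 0 by convention).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {img.shape}")
    if sigma_gradient_px <= 0 or sigma_window_px <= 0:
        raise ValueError("sigmas must be positive")

    gf = lambda a, order: ndimage.gaussian_filter(
        a, sigma_gradient_px, order=order, mode="reflect"
    )
    fx = gf(img, (0, 1))  # d/dx: derivative along columns
    fy = -gf(img, (1, 0))  # d/dy in math orientation: negated row derivative
    win = lambda a: ndimage.gaussian_filter(a, sigma_window_px, mode="reflect")
    jxx = win(fx * fx)
    jyy = win(fy * fy)
    jxy = win(fx * fy)

    energy = jxx + jyy
    diff = jxx - jyy
    root = np.sqrt(diff * diff + 4.0 * jxy * jxy)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = np.where(energy > 0, root / energy, 0.0)
    coherency = np.clip(coherency, 0.0, 1.0)

    # dominant eigenvector (gradient direction); fibers run perpendicular
    theta_grad = 0.5 * np.degrees(np.arctan2(2.0 * jxy, diff))
    theta = fold_axial_deg(theta_grad + 90.0)
    theta = np.where(energy > 0, theta, 0.0)
    return OrientationField(theta, energy, coherency, sigma_gradient_px, sigma_window_px)


def coherency_index(
    field: OrientationField,
    roi: RoiSpec | None = None,
    pixel_size_um: float = 1.0,
    min_energy_frac: float = MIN_ENERGY_FRAC,
    min_coherency: float = MIN_COHERENCY,
) -> float:
    """ROI-level coherency index: mean per-pixel coherency of energetic pixels.

    Pixels whose energy falls below ``min_energy_frac`` of the ROI maximum
    are excluded (they carry no orientation information); the boundary band
    is excluded as well. ``min_coherency`` is kept for interface symmetry
    with the distribution mask but does not gate the index itself — gating
    the averaged quantity on its own value would bias the summary upward.
    Returns 0.0 when every ROI pixel is masked out.
    """
    sel = field.interior_mask()
    if roi is not None:
        r0, r1, c0, c1 = roi.to_pixel_bounds(pixel_size_um, field.coherency.shape)
        box = np.zeros_like(sel)
        box[r0:r1, c0:c1] = True
        sel &= box
        if not box.any():
            raise ValueError("empty ROI")
    if not sel.any():
        return 0.0
    emax = field.energy[sel].max()
    if emax > 0:
        sel &= field.energy >= min_energy_frac * emax
    if not sel.any():
        return 0.0
    return float(field.coherency[sel].mean())


def _minmax(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min()
    if rng == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.min()) / rng


def angle_histogram(
    angles_deg: np.ndarray,
    bin_width_deg: float = 5.0,
    weights: np.ndarray | None = None,
    mask_description: str = "raw angles",
) -> OrientationHistogram:
    """Histogram of axial angles over (-90, 90] with a min-max-scaled copy."""
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size == 0:
        raise ValueError("no angles to histogram")
    n_bins = max(1, int(round(180.0 / bin_width_deg)))
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    # fold the single closed endpoint +90 into the last bin
    a = np.where(angles_deg == 90.0, np.nextafter(90.0, -90.0), angles_deg)
    counts, _ = np.histogram(a, bins=edges, weights=weights)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = counts.astype(float)
    return OrientationHistogram(centers, counts, _minmax(counts), mask_description)


def orientation_histogram(
    field: OrientationField,
    mask: np.ndarray | None = None,
    bin_width_deg: float = 5.0,
    weight_by_energy: bool = False,
) -> OrientationHistogram:
    """Orientation distribution of the selected pixels.

    ``mask`` defaults to the field's analysis mask (energy and coherency
    thresholds, border excluded). Raises on an empty mask.
    """
    if mask is None:
        mask = field.analysis_mask()
        desc = "analysis mask (energy/coherency thresholds)"
    else:
        desc = "user mask"
    if not mask.any():
        raise ValueError("empty pixel mask")
    w = field.energy[mask] if weight_by_energy else None
    return angle_histogram(field.theta_deg[mask], bin_width_deg, w, desc)


def orientation_color_map(
    field: OrientationField,
    brightness: np.ndarray | None = None,
) -> np.ndarray:
    """Hue-saturation-brightness rendering of an orientation field.

    Hue maps theta linearly from (-90, 90] onto the hue circle, saturation
    encodes coherency, brightness encodes the source image (if given) or the
    tensor energy, each min-max scaled. Returns an 8-bit RGB array.
    """
    hue = (field.theta_deg + 90.0) / 180.0 % 1.0
    sat = np.clip(field.coherency, 0.0, 1.0)
    val_src = np.asarray(brightness, float) if brightness is not None else field.energy
    val = _minmax(val_src)
    rgb = hsv_to_rgb(np.dstack([hue, sat, val]))
    return (np.rint(rgb * 255)).astype(np.uint8)
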