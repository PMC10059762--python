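"""Collagen quantification from SHG channels.

Two ROI-level metrics are computed per 100 x 100 um^2 window:

* collagen fraction = Nc / (Nc + Nb), the proportion of bright (collagen)
  pixels among all ROI pixels after binarization;
* collagen assembly degree (CAD), the intensity-weighted mean gray value of
  the SHG signal over gray levels 1..255 (gray 0 is background and is
  excluded from both numerator and denominator). CAD is computed on the raw
  intensities, not on the binarized mask, and serves as a proxy for collagen
  maturation and assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .core import MicrotissueImage, RoiSpec, grid_rois

__all__ = [
    "CollagenMask",
    "CollagenMetrics",
    "binarize_collagen",
    "collagen_fraction",
    "collagen_assembly_degree",
    "metrics_timecourse",
]


@dataclass
class CollagenMask:
    """Binary collagen/background classification of an SHG channel."""

    mask: np.ndarray  # bool, True = bright (collagen)
    threshold_value: int
    method: str  # "otsu" or "fixed"

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class CollagenMetrics:
    roi: RoiSpec
    collagen_fraction: float
    cad: float
    n_pixels: int
    threshold_value: int


def binarize_collagen(
    shg: np.ndarray,
    method: str = "otsu",
    fixed_threshold: int | None = None,
) -> CollagenMask:
    """Classify SHG pixels as collagen (bright) vs background.

    A pixel is bright iff its gray value strictly exceeds the threshold.
    With ``method="otsu"`` the threshold is computed from the image
    histogram; ``method="fixed"`` requires ``fixed_threshold`` in 0..255.
    """
    shg = np.asarray(shg)
    if shg.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {shg.shape}")
    if method == "otsu":
        if shg.max() == shg.min():
            thr = int(shg.max())  # constant image: nothing is bright
        else:
            thr = int(threshold_otsu(shg.astype(np.uint8)))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError('method="fixed" requires fixed_threshold')
        if not (0 <= fixed_threshold <= 255):
            raise ValueError("fixed_threshold must lie in 0..255")
        thr = int(fixed_threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CollagenMask(mask=shg > thr, threshold_value=thr, method=method)


def _roi_view(arr: np.ndarray, roi: RoiSpec | None, pixel_size_um: float) -> np.ndarray:
    if roi is None:
        view = arr
    else:
        r0, r1, c0, c1 = roi.to_pixel_bounds(pixel_size_um, arr.shape)
        view = arr[r0:r1, c0:c1]
    if view.size == 0:
        raise ValueError("ROI contains no pixels")
    return view


def collagen_fraction(
    mask: CollagenMask | np.ndarray,
    roi: RoiSpec | None = None,
    pixel_size_um: float = 1.0,
) -> float:
    """Fraction of bright pixels, Nc / (Nc + Nb), over the ROI.

    The denominator is the total ROI pixel count; the result lies in [0, 1]
    (multiply by 100 for the percent scale used in reporting).
    """
    m = mask.mask if isinstance(mask, CollagenMask) else np.asarray(mask, bool)
    view = _roi_view(m, roi, pixel_size_um)
    return float(view.mean())


def collagen_assembly_degree(
    shg: np.ndarray,
    roi: RoiSpec | None = None,
    pixel_size_um: float = 1.0,
) -> float:
    """Intensity-weighted mean gray value over levels 1..255 in the ROI.

    CAD = sum_i(i * p_i) / sum_i(p_i) for i in 1..255, where p_i is the
    number of ROI pixels at gray level i. Returns 0.0 when no pixel has
    gray >= 1.
    """
    shg = np.asarray(shg)
    if shg.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {shg.shape}")
    view = _roi_view(shg, roi, pixel_size_um)
    counts = np.bincount(view.astype(np.uint8).ravel(), minlength=256)
    levels = np.arange(256)
    denom = counts[1:].sum()
    if denom == 0:
        return 0.0
    return float((levels[1:] * counts[1:]).sum() / denom)


def metrics_timecourse(
    images: dict[str, list[MicrotissueImage]],
    rois: dict[str, list[RoiSpec]] | None = None,
    n_rois: int = 5,
    roi_size_um: float = 100.0,
    method: str = "otsu",
    fixed_threshold: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collagen metrics for a labeled image series.

    ``images`` maps timepoint labels to image lists. ROIs default to a
    deterministic grid of ``n_rois`` windows of ``roi_size_um`` per image;
    thresholding is per ROI. Returns (per-ROI table, per-timepoint summary
    with mean and SEM of both metrics).
    """
    rows = []
    for tp, imgs in images.items():
        if not imgs:
            raise ValueError(f"timepoint {tp!r} has no images")
        for k, img in enumerate(imgs):
            shg = img.shg
            img_rois = (
                rois[img.label or str(k)]
                if rois is not None
                else grid_rois(shg.shape, img.pixel_size_um, roi_size_um, n_rois)
            )
            for roi in img_rois:
                crop = roi.crop(shg, img.pixel_size_um)
                cmask = binarize_collagen(crop, method, fixed_threshold)
                rows.append(
                    {
                        "timepoint": tp,
                        "image": img.label or f"{tp}_img{k}",
                        "roi_id": roi.roi_id,
                        "n_pixels": crop.size,
                        "threshold": cmask.threshold_value,
                        "collagen_fraction": collagen_fraction(cmask),
                        "cad": collagen_assembly_degree(crop),
                    }
                )
    per_roi = pd.DataFrame(rows)
    summary = (
        per_roi.groupby("timepoint", sort=False)[["collagen_fraction", "cad"]]
        .agg(["mean", "sem", "count"])
        .reset_index()
    )
    summary.columns = ["_".join(c).rstrip("_") for c in summary.columns]
    return per_roi, summary
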