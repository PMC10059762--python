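"""Core containers shared across the analysis modules.

Conventions used package-wide:

* Images are 2D ``numpy`` arrays indexed ``[row, col]``; intensity images are
  8-bit (0-255) unless stated otherwise.
* Physical coordinates are in micrometres. ``x`` runs along columns, ``y``
  along rows, with the origin at the top-left pixel corner.
* Orientation angles are in degrees, measured counter-clockwise from the
  image horizontal axis in standard mathematical orientation (y pointing up),
  and lie in the half-open interval (-90, 90]. Because array rows increase
  downward, the mathematical y axis is the negated row axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RoiSpec", "MicrotissueImage", "fold_axial_deg"]


def fold_axial_deg(angles_deg: np.ndarray | float) -> np.ndarray | float:
    """Fold angles (degrees) into the axial range (-90, 90].

    Fiber orientation is axial: theta and theta+180 describe the same fiber.
    """
    folded = (np.asarray(angles_deg, dtype=float) + 90.0) % 180.0 - 90.0
    # map -90 -> +90 so the interval is half-open at the bottom
    folded = np.where(folded == -90.0, 90.0, folded)
    if np.isscalar(angles_deg) or np.ndim(angles_deg) == 0:
        return float(folded)
    return folded


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest in physical units (micrometres).

    The canonical analysis unit is a 100 x 100 um^2 window. ``x_um``/``y_um``
    give the top-left corner; ``y`` increases downward (row direction).
    """

    x_um: float
    y_um: float
    width_um: float = 100.0
    height_um: float = 100.0
    roi_id: str = ""

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um

    def to_pixel_bounds(
        self, pixel_size_um: float, shape: tuple[int, int] | None = None
    ) -> tuple[int, int, int, int]:
        """Return integer pixel bounds ``(row0, row1, col0, col1)``.

        Bounds are half-open slices. If ``shape`` is given, the ROI must lie
        inside the image, otherwise a ``ValueError`` is raised.
        """
        if pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        row0 = int(round(self.y_um / pixel_size_um))
        col0 = int(round(self.x_um / pixel_size_um))
        row1 = row0 + max(1, int(round(self.height_um / pixel_size_um)))
        col1 = col0 + max(1, int(round(self.width_um / pixel_size_um)))
        if shape is not None:
            nr, nc = shape
            if row0 < 0 or col0 < 0 or row1 > nr or col1 > nc:
                raise ValueError(
                    f"ROI {self} exceeds image bounds {shape} at "
                    f"pixel size {pixel_size_um} um/px"
                )
        return row0, row1, col0, col1

    def crop(self, img: np.ndarray, pixel_size_um: float) -> np.ndarray:
        r0, r1, c0, c1 = self.to_pixel_bounds(pixel_size_um, img.shape[:2])
        return img[r0:r1, c0:c1]


def grid_rois(
    image_shape: tuple[int, int],
    pixel_size_um: float,
    roi_size_um: float = 100.0,
    n_rois: int = 5,
) -> list[RoiSpec]:
    """Deterministic ROI placement: a centred grid of non-overlapping windows.

    Windows are laid out row-major on the largest centred grid that fits,
    then the first ``n_rois`` are returned. Raises if the image cannot hold
    ``n_rois`` disjoint windows.
    """
    nr, nc = image_shape
    side_px = roi_size_um / pixel_size_um
    per_row = int(nc // side_px)
    per_col = int(nr // side_px)
    if per_row * per_col < n_rois:
        raise ValueError(
            f"image {image_shape} px holds only {per_row * per_col} disjoint "
            f"{roi_size_um} um ROIs; {n_rois} requested"
        )
    off_y = (nr - per_col * side_px) / 2 * pixel_size_um
    off_x = (nc - per_row * side_px) / 2 * pixel_size_um
    rois = []
    for k in range(n_rois):
        i, j = divmod(k, per_row)
        rois.append(
            RoiSpec(
                x_um=off_x + j * roi_size_um,
                y_um=off_y + i * roi_size_um,
                width_um=roi_size_um,
                height_um=roi_size_um,
                roi_id=f"roi{k}",
            )
        )
    return rois


@dataclass
class MicrotissueImage:
    """Multichannel 2D micrograph with a physical pixel size.

    ``channels`` maps channel names ("shg", "gfp", "nuclei") to 2D uint8
    arrays of identical shape.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]

    @property
    def shg(self) -> np.ndarray:
        return self.channels["shg"]
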