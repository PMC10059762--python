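"""Synthetic microtissue images and microplate readings with known ground truth.

The generators emulate the three data streams the analysis consumes:

* SHG-like collagen channels: fields of anti-aliased thick line segments
  whose orientations follow an axial von Mises law (von Mises on the doubled
  angle), so ``kappa = 0`` gives exactly uniform orientations on (-90, 90]
  and the axial circular mean converges to ``mean_angle_deg``.
* GFP-like tumor-cell channels: Gaussian-profile blobs at known centers.
* MTT plates: optical densities following a Hill dose-response with
  multiplicative log-normal noise.

Every generator records its ground truth (masks, angle lists, centers,
curve parameters) so downstream metrics can be validated exactly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import MicrotissueImage, fold_axial_deg

__all__ = [
    "FiberFieldParams",
    "CellFieldParams",
    "PlateSpec",
    "FiberField",
    "CellField",
    "simulate_fiber_image",
    "simulate_cell_image",
    "simulate_scenario",
    "simulate_plate",
    "draw_axial_von_mises",
    "write_image",
]


# ---------------------------------------------------------------------------
# parameter records


@dataclass(frozen=True)
class FiberFieldParams:
    """Generative parameters for an SHG-like fiber field.

    ``target_coverage``, when set, overrides ``n_fibers``: segments are added
    until the ground-truth mask reaches the requested area fraction (feasible
    up to 0.95). ``fiber_intensity`` is either a single 8-bit gray value or a
    ``(low, high)`` pair sampled uniformly per fiber.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    n_fibers: int = 50
    mean_angle_deg: float = 0.0
    kappa: float = 0.0
    fiber_width_px: float = 3.0
    fiber_length_px: float = 40.0
    fiber_intensity: int | tuple[int, int] = 200
    background_noise_sd: float = 0.0
    target_coverage: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_size_px) <= 0:
            raise ValueError("image_size_px must be positive")
        if not (-90.0 < self.mean_angle_deg <= 90.0):
            raise ValueError("mean_angle_deg must lie in (-90, 90]")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be non-negative")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be non-negative")
        if self.target_coverage is not None:
            if not (0.0 <= self.target_coverage <= 1.0):
                raise ValueError("target_coverage must lie in [0, 1]")
            if self.target_coverage > 0.95:
                raise ValueError(
                    "target_coverage > 0.95 is unreachable with segment packing"
                )


@dataclass(frozen=True)
class CellFieldParams:
    """Generative parameters for a GFP-like cell field."""

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    n_cells: int = 50
    blob_radius_px: float = 4.0
    blob_intensity: int = 220
    min_separation_px: float = 0.0
    background_noise_sd: float = 0.0
    cluster_centers_px: tuple[tuple[float, float], ...] | None = None
    cluster_sd_px: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.blob_radius_px <= 0:
            raise ValueError("n_cells >= 0 and blob_radius_px > 0 required")
        if not (1 <= self.blob_intensity <= 255):
            raise ValueError("blob_intensity must be an 8-bit gray value")


@dataclass(frozen=True)
class PlateSpec:
    """Hill dose-response plate: OD(dose) = OD0 * [f + (1-f)/(1+(d/IC50)^h)]
    times multiplicative log-normal noise with coefficient of variation ``cv``.
    Dose 0 wells are vehicle controls with expected viability 100%.
    """

    doses_uM: tuple[float, ...] = (0.0, 10.0, 100.0, 1000.0, 10000.0)
    timepoints: tuple[str, ...] = ("24h", "48h", "72h")
    n_replicates: int = 3
    ic50_uM: float = 100.0
    hill_slope: float = 1.0
    od_control_mean: float = 0.8
    cv: float = 0.1
    floor_viability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.ic50_uM <= 0 or self.hill_slope <= 0:
            raise ValueError("ic50_uM and hill_slope must be positive")
        if not (0.0 <= self.floor_viability <= 1.0):
            raise ValueError("floor_viability must lie in [0, 1]")
        if any(d < 0 for d in self.doses_uM):
            raise ValueError("doses must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")


# ---------------------------------------------------------------------------
# result records


@dataclass
class FiberField:
    """A simulated SHG channel plus its generative ground truth."""

    image: MicrotissueImage
    mask: np.ndarray  # bool, True on fiber pixels
    angles_deg: np.ndarray  # one entry per fiber, in (-90, 90]
    params: FiberFieldParams

    @property
    def coverage(self) -> float:
        return float(self.mask.mean())


@dataclass
class CellField:
    image: MicrotissueImage
    centers_px: np.ndarray  # (n, 2) array of (row, col)
    params: CellFieldParams

    @property
    def centers_um(self) -> np.ndarray:
        return self.centers_px * self.params.pixel_size_um


# ---------------------------------------------------------------------------
# fiber rendering


def draw_axial_von_mises(
    rng: np.random.Generator, mean_angle_deg: float, kappa: float, n: int
) -> np.ndarray:
    """Draw axial orientations in degrees on (-90, 90].

    Sampling is von Mises on the doubled angle; halving maps the full circle
    onto the axial half-circle. kappa = 0 reduces to the uniform law.
    """
    doubled = rng.vonmises(np.deg2rad(2.0 * mean_angle_deg), kappa, size=n)
    return fold_axial_deg(np.rad2deg(doubled) / 2.0)


def _render_segment(
    canvas: np.ndarray,
    mask: np.ndarray,
    center: tuple[float, float],
    angle_deg: float,
    length: float,
    width: float,
    intensity: int,
) -> None:
    """Draw one anti-aliased thick segment in-place.

    The segment direction follows the package angle convention (math y up),
    so the row component of the direction is -sin(theta). Edge pixels get a
    linear coverage ramp of 1 px; the ground-truth mask is the set of pixels
    whose quantized gray exceeds half the fiber intensity, i.e. pixel centers
    within the geometric half-width.
    """
    nr, nc = canvas.shape
    th = np.deg2rad(angle_deg)
    d = np.array([-np.sin(th), np.cos(th)])  # (drow, dcol)
    c = np.asarray(center, dtype=float)
    p0, p1 = c - d * length / 2.0, c + d * length / 2.0
    pad = width / 2.0 + 1.5
    r0 = max(0, int(np.floor(min(p0[0], p1[0]) - pad)))
    r1 = min(nr, int(np.ceil(max(p0[0], p1[0]) + pad)) + 1)
    c0 = max(0, int(np.floor(min(p0[1], p1[1]) - pad)))
    c1 = min(nc, int(np.ceil(max(p0[1], p1[1]) + pad)) + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    pr = rr - p0[0]
    pc = cc - p0[1]
    seg = p1 - p0
    L2 = seg @ seg
    t = np.clip((pr * seg[0] + pc * seg[1]) / L2, 0.0, 1.0) if L2 > 0 else 0.0
    dist = np.hypot(pr - t * seg[0], pc - t * seg[1])
    cov = np.clip(width / 2.0 + 0.5 - dist, 0.0, 1.0)
    gray = np.rint(intensity * cov).astype(np.int64)
    patch = canvas[r0:r1, c0:c1]
    np.maximum(patch, gray, out=patch)
    mask[r0:r1, c0:c1] |= gray > intensity // 2


def simulate_fiber_image(params: FiberFieldParams) -> FiberField:
    """Render an SHG-like fiber field; deterministic for a given seed.

    Returns the 8-bit image, the boolean fiber mask and the per-fiber angle
    list. With ``target_coverage`` set, fibers are added until the mask
    reaches the target (within one fiber footprint, < 0.01 at defaults).
    """
    rng = np.random.default_rng(params.seed)
    nr, nc = params.image_size_px
    canvas = np.zeros((nr, nc), dtype=np.int64)
    mask = np.zeros((nr, nc), dtype=bool)
    angles: list[float] = []

    def intensity() -> int:
        if isinstance(params.fiber_intensity, tuple):
            lo, hi = params.fiber_intensity
            return int(rng.integers(lo, hi + 1))
        return int(params.fiber_intensity)

    def add_fiber() -> None:
        ang = float(
            draw_axial_von_mises(rng, params.mean_angle_deg, params.kappa, 1)[0]
        )
        center = (rng.uniform(0, nr), rng.uniform(0, nc))
        _render_segment(
            canvas,
            mask,
            center,
            ang,
            params.fiber_length_px,
            params.fiber_width_px,
            intensity(),
        )
        angles.append(ang)

    if params.target_coverage is None:
        for _ in range(params.n_fibers):
            add_fiber()
    else:
        stall = 0
        while mask.mean() < params.target_coverage:
            before = mask.sum()
            add_fiber()
            stall = stall + 1 if mask.sum() == before else 0
            if stall > 2000:
                raise RuntimeError(
                    f"coverage {params.target_coverage} unreachable: mask "
                    f"saturated at {mask.mean():.3f}"
                )

    img = canvas.astype(float)
    if params.background_noise_sd > 0:
        img = img + rng.normal(0.0, params.background_noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    mt = MicrotissueImage(
        channels={"shg": img},
        pixel_size_um=params.pixel_size_um,
        metadata={"generator": "simulate_fiber_image", "params": asdict(params)},
    )
    return FiberField(mt, mask, np.asarray(angles, dtype=float), params)


# ---------------------------------------------------------------------------
# cell rendering


def _place_centers(params: CellFieldParams, rng: np.random.Generator) -> np.ndarray:
    nr, nc = params.image_size_px
    # keep the full blob support (3 sigma = 1.5 r) inside the frame so
    # ground-truth centroids are well defined for detector validation
    margin = min(1.5 * params.blob_radius_px, nr / 4, nc / 4)
    centers: list[np.ndarray] = []
    n_clusters = (
        len(params.cluster_centers_px) if params.cluster_centers_px else 0
    )
    attempts = 0
    while len(centers) < params.n_cells:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError(
                f"could not place {params.n_cells} cells with separation "
                f"{params.min_separation_px} px in {params.image_size_px}"
            )
        if n_clusters:
            k = int(rng.integers(n_clusters))
            cand = np.asarray(params.cluster_centers_px[k]) + rng.normal(
                0.0, params.cluster_sd_px, size=2
            )
            if not (margin <= cand[0] < nr - margin and margin <= cand[1] < nc - margin):
                continue
        else:
            cand = np.array(
                [rng.uniform(margin, nr - margin), rng.uniform(margin, nc - margin)]
            )
        if params.min_separation_px > 0 and centers:
            d = np.hypot(*(np.array(centers) - cand).T)
            if d.min() < params.min_separation_px:
                continue
        centers.append(cand)
    return np.array(centers).reshape(-1, 2)


def simulate_cell_image(params: CellFieldParams) -> CellField:
    """Render a GFP-like channel with exactly ``n_cells`` Gaussian blobs.

    Blob profile: ``I(r) = blob_intensity * exp(-r^2 / (2 sigma^2))`` with
    ``sigma = blob_radius_px / 2``, truncated at 3 sigma. Pairwise center
    distances respect ``min_separation_px`` (rejection sampling).
    """
    rng = np.random.default_rng(params.seed)
    nr, nc = params.image_size_px
    centers = _place_centers(params, rng)
    canvas = np.zeros((nr, nc), dtype=float)
    sigma = params.blob_radius_px / 2.0
    ext = int(np.ceil(3 * sigma))
    for r, c in centers:
        r0, r1 = max(0, int(r) - ext), min(nr, int(r) + ext + 1)
        c0, c1 = max(0, int(c) - ext), min(nc, int(c) + ext + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        d2 = (rr - r) ** 2 + (cc - c) ** 2
        np.maximum(
            canvas[r0:r1, c0:c1],
            params.blob_intensity * np.exp(-d2 / (2 * sigma**2)),
            out=canvas[r0:r1, c0:c1],
        )
    if params.background_noise_sd > 0:
        canvas = canvas + rng.normal(0.0, params.background_noise_sd, canvas.shape)
    img = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    mt = MicrotissueImage(
        channels={"gfp": img},
        pixel_size_um=params.pixel_size_um,
        metadata={"generator": "simulate_cell_image", "params": asdict(params)},
    )
    return CellField(mt, centers, params)


# ---------------------------------------------------------------------------
# named scenarios


@dataclass
class ScenarioTimepoint:
    timepoint: str
    image: MicrotissueImage
    fiber_mask: np.ndarray
    fiber_angles_deg: np.ndarray
    cell_centers_px: np.ndarray
    erased_fraction: float


@dataclass
class Scenario:
    name: str
    seed: int
    kappa: float
    mean_angle_deg: float
    timepoints: list[ScenarioTimepoint]


#: scenario parameter sets; "tumor_like" mimics an aligned, partially
#: degraded tumor matrix with clustered cancer cells, "stroma_like" a dense
#: isotropic fibroblast matrix without cancer cells.
SCENARIOS: dict[str, dict] = {
    "tumor_like": dict(
        kappa=8.0,
        mean_angle_deg=-30.0,
        coverages=(0.15, 0.15, 0.15),
        erased_fractions=(0.0, 0.15, 0.30),
        n_cells=(30, 45, 60),  # proliferating cancer cells
        clustered=True,
    ),
    "stroma_like": dict(
        kappa=0.0,
        mean_angle_deg=0.0,
        coverages=(0.20, 0.25, 0.30),
        erased_fractions=(0.0, 0.0, 0.0),
        n_cells=(0, 0, 0),
        clustered=False,
    ),
}

TIMEPOINT_LABELS = ("day4", "day8", "day12")


def simulate_scenario(
    name: str,
    seed: int = 0,
    image_size_px: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.5,
    noise_sd: float = 4.0,
    overrides: dict | None = None,
) -> Scenario:
    """Generate a three-timepoint image series for a named scenario.

    ``tumor_like``: concentrated orientations (kappa 8) around -30 degrees,
    clustered GFP cells, and progressive random erasure of fiber pixels to
    mimic matrix degradation. ``stroma_like``: isotropic (kappa 0), denser
    coverage growing over time, no GFP channel content.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    cfg = {**SCENARIOS[name], **(overrides or {})}  # e.g. null controls
    root = np.random.default_rng([seed, zlib.crc32(name.encode()) % (2**31)])
    tps: list[ScenarioTimepoint] = []
    for i, label in enumerate(TIMEPOINT_LABELS):
        sub_seed = int(root.integers(2**31))
        fib = simulate_fiber_image(
            FiberFieldParams(
                image_size_px=image_size_px,
                pixel_size_um=pixel_size_um,
                mean_angle_deg=cfg["mean_angle_deg"],
                kappa=cfg["kappa"],
                target_coverage=cfg["coverages"][i],
                background_noise_sd=0.0,
                seed=sub_seed,
            )
        )
        shg = fib.image.shg.astype(float)
        mask = fib.mask.copy()
        erased = cfg["erased_fractions"][i]
        erng = np.random.default_rng([sub_seed, 1])
        if erased > 0:
            idx = np.flatnonzero(mask)
            kill = erng.choice(idx, size=int(erased * idx.size), replace=False)
            flat = shg.ravel()
            flat[kill] = 0.0
            mask.ravel()[kill] = False
        if noise_sd > 0:
            shg = shg + erng.normal(0.0, noise_sd, shg.shape)
        shg = np.clip(np.rint(shg), 0, 255).astype(np.uint8)

        n_cells_tp = cfg["n_cells"][i]
        if n_cells_tp > 0:
            nr, nc = image_size_px
            clusters = (
                tuple(
                    (float(erng.uniform(0.2 * nr, 0.8 * nr)),
                     float(erng.uniform(0.2 * nc, 0.8 * nc)))
                    for _ in range(3)
                )
                if cfg["clustered"]
                else None
            )
            cells = simulate_cell_image(
                CellFieldParams(
                    image_size_px=image_size_px,
                    pixel_size_um=pixel_size_um,
                    n_cells=n_cells_tp,
                    min_separation_px=6.0,
                    background_noise_sd=noise_sd,
                    cluster_centers_px=clusters,
                    seed=int(erng.integers(2**31)),
                )
            )
            gfp = cells.image.channel("gfp")
            centers = cells.centers_px
        else:
            gfp = np.zeros(image_size_px, dtype=np.uint8)
            centers = np.empty((0, 2))

        img = MicrotissueImage(
            channels={"shg": shg, "gfp": gfp},
            pixel_size_um=pixel_size_um,
            label=f"{name}_{label}",
            metadata={"scenario": name, "timepoint": label, "seed": seed},
        )
        tps.append(
            ScenarioTimepoint(label, img, mask, fib.angles_deg, centers, erased)
        )
    return Scenario(name, seed, cfg["kappa"], cfg["mean_angle_deg"], tps)


# ---------------------------------------------------------------------------
# plates


def hill_viability(dose_uM, ic50_uM: float, hill_slope: float, floor: float):
    """Expected viability fraction at a dose under the Hill model."""
    dose = np.asarray(dose_uM, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (dose / ic50_uM) ** hill_slope, 0.0)
    return floor + (1.0 - floor) / (1.0 + ratio)


def simulate_plate(spec: PlateSpec) -> pd.DataFrame:
    """Simulate OD readings; one plate per timepoint, one row per dose.

    Returns a tidy table with columns well, row, col, dose_uM, timepoint, od.
    Noise is multiplicative log-normal with unit mean and coefficient of
    variation ``cv``, so all ODs are strictly positive.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.cv**2))
    rows = []
    for tp in spec.timepoints:
        for i, dose in enumerate(spec.doses_uM):
            expected = spec.od_control_mean * hill_viability(
                dose, spec.ic50_uM, spec.hill_slope, spec.floor_viability
            )
            for j in range(spec.n_replicates):
                noise = (
                    np.exp(rng.normal(-(sigma**2) / 2.0, sigma))
                    if spec.cv > 0
                    else 1.0
                )
                rows.append(
                    {
                        "well": f"{chr(ord('A') + i)}{j + 1}",
                        "row": chr(ord("A") + i),
                        "col": j + 1,
                        "dose_uM": dose,
                        "timepoint": tp,
                        "od": float(expected * noise),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def write_image(img: MicrotissueImage, path: str | Path, ground_truth: dict | None = None) -> None:
    """Write channels as a multi-page TIFF with the pixel size in metadata;
    ground truth, if given, goes to a JSON sidecar next to the image."""
    path = Path(path)
    stack = np.stack([img.channels[ch] for ch in sorted(img.channels)])
    res = 1.0 / img.pixel_size_um  # pixels per micrometre
    tifffile.imwrite(
        path,
        stack,
        resolution=(res, res),
        metadata={
            "axes": "CYX",
            "channels": sorted(img.channels),
            "pixel_size_um": img.pixel_size_um,
            "unit": "um",
        },
    )
    if ground_truth is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(_jsonable(ground_truth), indent=2))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
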