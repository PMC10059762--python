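#!/usr/bin/env python
"""Generate the synthetic study material: tumor-like and stroma-like
microtissue image series (three timepoints each) and an MTT plate.

Images and ground-truth sidecars go to scratch/analysis/images (binary, not
part of the deliverable); the plate OD table and a ground-truth summary go
to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from mtq.synthdata import PlateSpec, simulate_plate, simulate_scenario, write_image

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    img_dir = ROOT / "scratch" / "analysis" / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    res_dir = ROOT / "results"
    res_dir.mkdir(exist_ok=True)

    rows = []
    for name in ("tumor_like", "stroma_like"):
        scn = simulate_scenario(name, seed=args.seed, image_size_px=(512, 512))
        for tp in scn.timepoints:
            write_image(
                tp.image,
                img_dir / f"{name}_{tp.timepoint}.tif",
                {
                    "angles_deg": tp.fiber_angles_deg,
                    "cell_centers_px": tp.cell_centers_px,
                    "erased_fraction": tp.erased_fraction,
                },
            )
            rows.append(
                {
                    "scenario": name,
                    "timepoint": tp.timepoint,
                    "kappa": scn.kappa,
                    "mean_angle_deg": scn.mean_angle_deg,
                    "mask_coverage": tp.fiber_mask.mean(),
                    "n_fibers": len(tp.fiber_angles_deg),
                    "n_cells": len(tp.cell_centers_px),
                    "erased_fraction": tp.erased_fraction,
                }
            )
    truth = pd.DataFrame(rows)
    truth.to_csv(res_dir / "ground_truth_summary.csv", index=False)

    od = simulate_plate(PlateSpec(cv=0.1, seed=args.seed))
    od.to_csv(res_dir / "plate_od.csv", index=False)

    print(f"wrote {len(rows)} images to {img_dir}")
    print(truth.to_string(index=False))
    print(f"plate: {len(od)} wells -> {res_dir / 'plate_od.csv'}")


if __name__ == "__main__":
    main()
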