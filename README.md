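# mtq — microtissue quantification

`mtq` is a tested, reusable implementation of the image-quantification and
viability workflow used to characterize bioengineered colorectal-cancer
microtissues: label-free second-harmonic-generation (SHG) collagen metrics,
structure-tensor fiber-orientation analysis, GFP cancer-cell counting, MTT
dose–response viability, and the accompanying statistics. Because studies of
this kind rarely deposit their raw micrographs or plate readings, the
package ships a first-class synthetic-data module that generates SHG-like
fiber networks, GFP-like cell fields and Hill dose–response plates **with
known ground truth**, so every metric in the pipeline is validated against
the quantities used to generate its input.

It is aimed at groups doing 3D tumor-microenvironment models who want the
standard Fiji/OrientationJ-style readouts as scriptable, seedable Python.

## The quantities it computes

For each 100 × 100 µm² region of interest (ROI) of an SHG collagen channel:

* **Collagen fraction** — after binarization (per-ROI Otsu by default),
  the proportion of bright (collagen) pixels,
  `fraction = Nc / (Nc + Nb)`, with `Nc` collagen and `Nb` background pixels.
* **Collagen assembly degree (CAD)** — the intensity-weighted mean gray
  value over levels 1–255 (gray 0 excluded),
  `CAD = Σᵢ i·pᵢ / Σᵢ pᵢ`, `pᵢ` = pixels at gray level `i`; a proxy for
  collagen maturation.
* **Orientation, energy, coherency** — per pixel from the structure tensor
  `J = G_σ ∗ [fx², fx fy; fx fy, fy²]`:
  orientation `θ ∈ (−90°, 90°]` (smallest-eigenvalue eigenvector), energy
  `tr J`, coherency `√((Jxx−Jyy)² + 4Jxy²) / tr J ∈ [0, 1]`. ROI summaries:
  the **coherency index** (mean coherency of energetic pixels; 1 = fully
  aligned fibers, 0 = isotropic) and a min–max-normalized orientation
  histogram.
* **Cell density** — automated GFP blob detection (smoothing, background
  subtraction, watershed splitting), reported as cells/µm² per ROI.
* **Viability (%)** — `100 × OD_treated / OD_control` per well, with the
  control OD taken as the mean of that plate-and-timepoint's vehicle wells,
  plus an optional Hill fit
  `v(d) = 100·[f + (1−f)/(1 + (d/IC50)^h)]`.
* **Statistics** — Friedman test for blocked time courses, one-way ANOVA
  with Tukey HSD for group comparisons, mean ± SEM summaries.

## Worked example

```python
from mtq.synthdata import FiberFieldParams, simulate_fiber_image
from mtq.segmetrics import binarize_collagen, collagen_fraction, collagen_assembly_degree
from mtq.orientation import structure_tensor_field, coherency_index, orientation_histogram

fib = simulate_fiber_image(FiberFieldParams(
    image_size_px=(512, 512), mean_angle_deg=-30, kappa=8,
    target_coverage=0.15, background_noise_sd=4, seed=0))

mask = binarize_collagen(fib.image.shg, "otsu")
print(f"ground-truth coverage {fib.coverage:.3f}, "
      f"Otsu collagen fraction {collagen_fraction(mask):.3f}")
print(f"CAD {collagen_assembly_degree(fib.image.shg):.1f}")

field = structure_tensor_field(fib.image.shg, sigma_window_px=4)
print(f"coherency index {coherency_index(field):.3f}")
print(f"modal orientation {orientation_histogram(field).modal_angle_deg:+.1f} deg")
```

prints

```
ground-truth coverage 0.150, Otsu collagen fraction 0.154
CAD 56.0
coherency index 0.840
modal orientation -32.5 deg
```

— the thresholded fraction recovers the generator's coverage to ~0.005 and
the orientation analysis recovers the von Mises mean (−30°) within one
5-degree bin, with the high coherency expected at concentration κ = 8. The
CAD of 56 on a frame whose fibers sit at gray 200 illustrates a property of
the metric worth knowing: it averages over *every* pixel with gray ≥ 1, so
low-gray background noise dilutes it (on the same field rendered without
noise it is 151.3). Comparisons are therefore meaningful between images
with similar background statistics — which is how it is used here.

The same operations are available from the shell via the `mtq` CLI
(`mtq simulate fibers`, `mtq metrics`, `mtq orient`, `mtq cells`,
`mtq viability`, `mtq stats`, `mtq demo`), and the numbered scripts under
`analysis/` run the complete study narrative: `01_simulate.py` generates
the tumor-like (aligned, partially degraded matrix, clustered GFP cells)
and stroma-like (isotropic, dense matrix) series, `02`–`05` quantify
collagen, orientation, cell counts and viability, and `06_demo_report.py`
runs the end-to-end comparison, writing tables to `results/`.

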