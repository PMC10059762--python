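# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `mtq`. The workflow quantifies extracellular-matrix
remodeling in 3D tumor microtissues from SHG collagen channels, cancer-cell
distribution from GFP channels, and drug response from MTT optical
densities; because such studies rarely deposit raw data, validation is
against synthetic inputs with known ground truth.

## Conventions

* Images are 2D `uint8` arrays `[row, col]`; physical coordinates in µm
  with x along columns, y along rows, origin top-left.
* Orientation angles are axial (a fiber at θ and θ+180° is the same fiber),
  in degrees, counter-clockwise from the image horizontal in standard
  mathematical orientation (y up), range (−90°, 90°]. Since rows grow
  downward, gradients use the negated row derivative. This one convention
  is used by the generator, the structure tensor, histograms and color maps.
* The analysis unit is a 100 × 100 µm² ROI; the default grid placement is
  deterministic (centred, row-major) so runs are reproducible.

## Synthetic data generators

**Fiber fields.** Collagen is rendered as anti-aliased straight segments
(length 40 px, width 3 px, gray 200 by default) with centers uniform in the
frame — the simplest model producing elongated SHG-like structures.
Orientations follow an *axial von Mises* law: a von Mises draw on the
doubled angle, halved. This makes κ = 0 exactly uniform on (−90°, 90°] and
the axial circular mean converge to the requested mean angle; a plain von
Mises folded into the half-circle would do neither cleanly. The per-pixel
edge ramp spans 1 px; the ground-truth mask is the set of pixels whose
quantized gray exceeds half the fiber intensity, i.e. pixel centers inside
the geometric half-width. When `target_coverage` is set, segments are added
until the mask reaches the target; each segment adds ≲ 0.003 coverage at
the defaults, so the overshoot is far inside the ±0.02 contract (feasible
up to 0.95, enforced). Image noise is additive Gaussian, clipped to the
8-bit range — 8-bit output matches the 1–255 gray range over which the
assembly degree is defined.

**Scenarios.** `tumor_like` emulates an aligned, remodeled tumor matrix:
κ = 8 around −30°, 15% coverage, clustered GFP cells growing 30 → 45 → 60
per 512² frame over the three timepoints, and progressive random erasure of
fiber pixels (0, 15, 30%) standing in for proteolytic degradation — an
image-level surrogate, not a biological model. `stroma_like` emulates a
dense healthy matrix: κ = 0 (isotropic), coverage growing 0.20 → 0.30, no
cancer cells. Defaults: 0.5 µm/px (an explicit configuration choice, not an
inferred acquisition fact), Gaussian noise σ = 4.

**Cell fields.** Cells are Gaussian-profile blobs (σ = radius/2, truncated
at 3σ, peak gray 220), placed by rejection sampling under a minimum
pairwise separation; blob supports are kept wholly inside the frame so
ground-truth centroids are well defined for detector validation.

**Plates.** OD(dose) = OD₀ · [f + (1−f)/(1+(d/IC50)^h)] times log-normal
noise with unit mean and coefficient of variation `cv` (so ODs are strictly
positive and the replicate CV equals `cv`). Defaults mirror a
five-point 5-FU design — 0, 10, 100 µM, 1 mM, 10 mM at 24/48/72 h,
triplicate wells — with IC50 = 100 µM, h = 1, OD₀ = 0.8, cv = 0.1.

## Collagen metrics

Binarization defaults to per-ROI Otsu (no bright/dark rule is standard
enough to hard-code; a fixed threshold is available). A pixel is collagen
iff gray > threshold; the fraction is Nc/(Nc+Nb) over the ROI, reported as
a proportion (percent is a display choice). The assembly degree is the mean
gray over levels 1–255 — gray 0 is excluded from numerator *and*
denominator, a literal reading of the summation bounds — computed on raw
intensities, not the mask. Consequence: low-gray background noise dilutes
CAD (see the README example), so CAD comparisons should hold background
statistics fixed. Both metrics are tested for exact agreement with naive
per-pixel loops.

## Structure-tensor orientation analysis

Gradients are Gaussian derivatives (σ_gradient = 1 px; a spline-based
gradient would be the plugin-faithful alternative, this choice is the
standard well-conditioned one), the tensor is smoothed by a Gaussian window
σ_window, and orientation/energy/coherency follow the closed forms
θ_fiber = ½·atan2(2Jxy, Jxx−Jyy) + 90° (folded), E = tr J,
C = √((Jxx−Jyy)² + 4Jxy²)/tr J. All convolutions use reflective padding; a
border band of 3σ is flagged and excluded from ROI statistics. A constant
image yields E = C = 0 with θ = 0 by convention. Per-pixel values are
verified against an independent 2×2 eigendecomposition oracle to 1e−6 and
against closed-form gratings to 2°.

**Window size.** `structure_tensor_field` defaults to σ_window = 1 px, the
setting familiar from interactive plugin use. For ROI-level *alignment*
summaries the pipeline uses σ_window = 4 px (2 µm at the default pixel
size), and this is deliberate: with a window smaller than one fiber, every
pixel sees a single clean edge and coherency is ≈ 0.9 even for a fully
isotropic field — the statistic measures edge sharpness, not alignment
between fibers. It also inverts under speckle degradation, which corrupts
edges but not global alignment. A window wider than the fiber spacing mixes
neighboring fibers, so coherency rises with the orientation concentration κ
as intended (≈ 0.72 at κ = 0 vs ≈ 0.86 at κ = 32 at these defaults). The
absolute index therefore depends on σ_window relative to the texture scale,
and only contrasts computed at the same settings are comparable.

**Thresholds.** The coherency index masks pixels below 2% of the ROI's
maximum energy (relative, matching plugin semantics) — they carry no
orientation information — but is *not* gated on coherency itself, which
would bias the averaged quantity upward; the 20% coherency cutoff applies
to distribution masks (histograms, maps). An all-masked ROI returns 0.
Orientation histograms use 5° bins over (−90°, 90°] and include a
min–max-normalized copy ((x−min)/(max−min); constant input → zeros with a
warning). The HSB map encodes θ as hue, coherency as saturation, and the
source image (or energy) as brightness.

## Cell counting

Detection: Gaussian smoothing at σ = radius/2, background subtraction
(large-σ Gaussian), Otsu threshold, local maxima at least one radius apart
seeding a watershed over the foreground, one intensity-weighted centroid
per basin. Saturated frames are flagged rather than guessed at. On the
synthetic conditions (radius 4 px, separation ≥ 2 radii, noise σ = 5) the
detector recovers 200/200 blobs per 512² frame across seeds; real GFP
images with overlapping or out-of-focus cells will do worse, and the tests
quantify generator recovery, not human-level counting. Densities are
count/area per ROI with per-timepoint mean ± SEM over the 4-images ×
5-ROIs reporting design.

## Viability and dose response

Viability (%) = 100·OD_treated/OD_control with OD_control the mean of that
plate-and-timepoint's vehicle (dose 0) wells — standard MTT practice; thus
vehicle wells average exactly 100% by construction, and scaling a plate by
any constant leaves viability unchanged. Negative ODs (blank
over-subtraction) clip to 0 with a warning; blank subtraction itself is off
by default. The Hill fit is least squares on the generator's own
four-parameter logistic with IC50 parameterized on the log scale, bounds
keeping slope and floor physical, and standard errors from the covariance
(delta method for IC50). A monotone-increasing dose–viability relationship
(Spearman ρ > 0.5 over positive doses) is flagged non-fittable instead of
being forced through the model.

## Statistics

Friedman (within-block ranks, average-rank ties) serves blocked time
courses — blocks are culture replicates, conditions are timepoints, the
standard design when n ≥ 3 replicates are followed over time. One-way
ANOVA + Tukey HSD (studentized range) serves independent-group
comparisons; α = 0.05. Degenerate inputs (all-constant) return the null
result rather than NaN. Type-I error of both tests is verified by null
simulation at 1000 replicates: 20 blocks × 3 conditions for Friedman —
enough blocks for the χ² approximation to hold its level, which it does not
reliably do below ~10 blocks — and 3 × n=10 groups for ANOVA/Tukey, with
rejection rates required inside the binomial 95% band around 0.05.
Min–max scaling is implemented literally; it rescales the range and does
not normalize distribution shape.

## What passing tests do and do not show

The generators reproduce the *statistical structure* the analysis assumes:
elongated bright structures with controllable coverage and an axial
orientation law, isolated bright blobs, multiplicative plate noise. They
omit optical physics (PSF, depth attenuation, speckle), fiber curvature and
branching, cell morphology, and spatial OD artifacts (edge effects,
evaporation). Passing therefore certifies the *computational* correctness
and calibration of the pipeline — metrics equal their definitions, the
tensor equals its eigendecomposition, estimators recover generative
parameters, tests hold their nominal level — not performance on real
micrographs. The scenario comparison (tumor-like coherency > stroma-like,
preferential orientation band near −30°, selective viability loss at low
IC50) is a directional reproduction of the study design, not a numerical
one: published values from undeposited biological samples cannot anchor
desk-scale tests.

## Problem sizes

Defaults were chosen so the full suite runs in minutes on one CPU: 512²
demonstration frames (256² in unit tests), 10 replicates per scenario in
the demonstration and acceptance runs, 1000-replicate null simulations,
20-seed Hill-recovery studies. All randomness flows from explicit seeds;
the pipeline splits one root generator per stage so stages are
independently reproducible.
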