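# Methods

## Conventions and geometry

A cell is a `(channel, z, y, x)` intensity stack with physical voxel sizes
`(dz, dy, dx)` in µm. The axial convention is fixed at load time: **slice 0
is the slice nearest the coverslip** (the immune-synapse side); files
acquired top-down are re-indexed on read. The default acquisition geometry
mirrors spinning-point confocal practice for B cells: 0.14 µm z-step and
0.2 µm pixels. Intensities are kept in native dtype, never rescaled, and no
background subtraction is applied at read time; computations promote to
float64 internally.

The synapse-plane slab is the first `⌈f·n_z⌉` slices with `f = 0.10` by
default. The ceiling guarantees a non-empty slab for any stack depth; with
the 20-slice default that is 2 slices (0.28 µm), with 24 slices it is 3.

## Per-cell statistics

**Z-scan and synapse fraction.** Per-slice sums of a channel are taken over
the cell mask (robust to off-cell debris; a whole-frame mode is available
since macro-style analyses sometimes sum the full field). Percentages are
`100·raw_k/Σraw`; they sum to 100 by construction and the whole-cell
fluorescence is computed with the identical summation order so the identity
`wcf = Σ raw_k` is bitwise exact. A zero whole-cell total raises rather
than emitting NaN rows.

**Polarity index.** Computed in physical units so anisotropic z is handled
correctly. C is the geometric centroid of the cell mask, F the
intensity-weighted centroid of the channel inside the mask, û the unit
vector from C to the annotated bead, and R the distance from C to the mask
boundary along û, found by marching the ray at quarter-voxel steps and
keeping the last in-mask sample. The index `((F−C)·û)/R` is clamped to
[−1, 1] with a warning if discretization pushes it past the bounds. Bead
positions are annotations (latex beads are unlabeled), not detections.

**Pearson colocalization.** Plain Pearson r over the voxels of
`cell_mask ∩ synapse slab`, with no Costes thresholding — the headline
coefficient of the standard Fiji Coloc2 readout. Zero variance in either
channel is an error (r is undefined), not a silent 0.

**MTOC detection and proximal density.** The MTOC is the maximum of the
Gaussian-smoothed tubulin channel inside the cell mask (σ = 1 px in XY,
0.5 slice in z — enough to suppress shot noise without displacing the
maximum); ties break deterministically to the lowest (z, y, x). The
density circle is drawn in physical µm (presets: 4 µm for A20, 2 µm for
primary B cells) on the MTOC slice ± 1; a pixel belongs to the circle when
its center satisfies the disc inequality (no partial-pixel weighting), the
three slices' voxels are pooled into one mean, and the circle is *not*
intersected with the cell mask, matching how such a circle is drawn
interactively. At an edge slice the missing neighbor is dropped (2-slice
cylinder) with a warning.

**Line scans** sample a slice by bilinear interpolation at
`⌊length⌋ + 1` evenly spaced points (≈ 1 px spacing); even spacing rather
than exact unit steps makes profile reversal an exact symmetry.

**Morphometry.** ER masks come from Otsu's threshold computed *within the
cell mask*: off-cell background would dominate a whole-frame histogram.
One guard is applied before thresholding: intensities are capped at their
99.5th percentile, because a few extremely bright voxels (a saturated
perinuclear focus) otherwise stretch the histogram until Otsu separates
the bright tail from the rest instead of background from signal. Area at
the synapse plane is the XY projection (binary OR) of the thresholded ER
over the slab times the pixel area — the slab, not a single slice, defines
"the plane of the IS". Volume follows the 3D-Objects-Counter convention:
26-connected components, components below `min_object_voxels = 5`
discarded as noise speckle (the size filter of the original tool is not
documented anywhere; 5 voxels ≈ 0.03 µm³ only rejects speckle), summed
voxel count × voxel volume. Blank channels yield area/volume 0 with a
warning — legitimate for unspread cells.

**Segmentation.** Gaussian smoothing, Otsu, 3-D closing, hole filling,
largest connected component. Two implementation details matter on real
cortical-shell-like images: closing runs on an edge-padded array (plain
closing erodes voxels on the border-touching coverslip slice), and holes
are filled slice-wise in 2-D before the 3-D fill (a cortical shell is open
toward the coverslip face, so the 3-D interior is not topologically a
hole). A user-supplied 0/255 mask TIFF can replace the automatic mask to
reproduce hand-drawn ROIs exactly. A full 3-D mask is used rather than one
2-D ROI applied to all slices; for the intensity-sum statistics here the
difference is small but documented.

**Group statistics.** Cells are independent observations pooled across
runs (no per-experiment nesting — a documented simplification). Two
conditions: classical equal-variance Student's t-test; three or more:
one-way ANOVA plus Tukey HSD on the pooled-variance model. Identical data
in all groups reports F = 0, p = 1 by convention instead of a 0/0
statistic. Summaries are mean ± SEM with the usual star thresholds
(0.05, 0.01, 0.001, 0.0001).

## The synthetic-cell generator

The generator exists so that every statistic can be validated against a
known answer. Its central contract: **truth is measured, not requested.**
Every `SceneTruth` field is recomputed from the noise-free stack by direct
per-voxel summation; requested and realized values must agree within a
stated tolerance (1% for the bottom fraction) or generation fails loudly.
Recovery tests therefore test the pipeline, not the generator's
calibration. `(params, seed)` determines the stack bit-for-bit.

**Coverslip cells.** A hemispheroid (default radius 5 µm, height 2.2 µm —
an A20-like cell spread on glass, fitting a 20 × 0.14 µm stack) rests on
slice 0. Actin is a thin cortical shell just inside the membrane, which at
the bottom slices reads as the classic spreading ring. Tubulin is a
textured diffuse pool (microtubule density is heterogeneous — this texture
is what makes ER–tubulin coupling measurable in any sub-ROI), a bright
MTOC punctum, and an aster of decaying rays that start 0.5 µm from the
MTOC so no unphysical hot voxel accumulates. The ER channel mixes three
unit-mass components on an inner support: an axially weighted textured
field, a copy of the tubulin pattern (weight = the coupling parameter),
and a Gaussian perinuclear pool at the MTOC. The axial profile is
exponential in z with rate λ solved (Brent's method on the monotone
slab-share function, computed with overflow-safe shifted exponents) so the
noise-free slab share equals the requested bottom fraction; λ may be
negative, since a hemispheroid's uniform slab share (≈ 0.18 at defaults)
exceeds small requested fractions.

When a target ER volume is set, the support becomes a *reticular network*:
the brightest voxels of a smoothed random field inside the support region,
selected to match the target voxel count exactly. Two optional selection
biases shape the network without changing its volume — toward the MTOC
(perinuclear densification upon activation) and toward the coverslip (the
synaptic ER sheet). Noise is Poisson on the expected counts (per-voxel
means near 80, peaks around 200–300) followed by Gaussian read noise
(σ = 2 counts), clipped at zero; an optional anisotropic Gaussian PSF blur
(off by default — the metrics are intensity-sum statistics largely
insensitive to modest blur) is applied before noise.

**Bead conjugates.** A sphere (radius 4 µm) in a taller stack, bead placed
adjacent along +y. The ER is a uniform floor (15% of mass, keeping the
cell segmentable) plus a Gaussian blob displaced by
`polarization × 0.8 × radius` along the cell–bead axis. The recorded truth
is the noise-free centroid displacement projected on the axis and
normalized by the cell radius; truncation by the cell boundary means
realized truth saturates near ±0.45 for requested ±0.8 — as in real cells,
a fully polarized distribution does not put its centroid on the membrane.
Coverslip-style slab statistics are not computed in bead mode (there is no
coverslip plane); the polarity index is the bead-mode statistic.

**What the generator does not emulate**, and hence what passing recovery
tests do and do not show: real PSF side lobes and spectral bleed-through;
membrane-contact-site microstructure; sheet/tubule morphology beyond the
network texture; live-cell dynamics; multi-cell fields. Recovery under
this model demonstrates that the estimators are unbiased and correctly
normalized under realistic counting noise and geometry — not that
segmentation would survive arbitrary real-world artifacts.

## The phenotype demo

`run_demo` builds four conditions — resting, activated on 0.3 kPa gel, on
13 kPa gel, and on glass — that encode the expected biology: stiffer
substrates give larger spreading radii and flatter cells, higher synapse
fractions (0.25 / 0.28 / 0.33 / 0.36 requested), lower ER–tubulin coupling
(0.60 / 0.60 / 0.45 / 0.30), and stronger MTOC pooling (pool fractions
0.02–0.30 plus network bias). Every condition paints the *same* 30 µm³ of
ER and the same total photon count: activation redistributes the ER
without net growth, so the volume and whole-cell-fluorescence nulls hold
by construction. Per-cell lognormal jitter is applied to radius and height
(4%), expression level (12% — transient transfection varies widely), and
ER content (scaled with cell size plus 3% scatter, which keeps the network
fill factor stable and the target always within the support's capacity).
With 10 cells per condition all ten ordering checks pass for every seed
0–9; the check list reports PASS/FAIL per phenotype rather than asserting,
so a null suite (all conditions identical) correctly reports
non-significance.

## Numerical choices and degenerate inputs

- Thresholds on float data use scikit-image's 256-bin Otsu; the
  hot-pixel cap (above) is the only preprocessing.
- The axial-rate solver brackets λ in [−40, 40] with `xtol = 1e−12`;
  unreachable fractions (given the coupled components' fixed axial mass)
  raise with the attainable range in the message.
- Mask centroids and boundary distances use voxel centers at
  `index × spacing`.
- Segmentation errors (blank image, empty mask, > 50% of voxels in the
  mask) and statistic errors (zero variance, zero total fluorescence, bead
  on the centroid) raise typed exceptions; the batch runner logs them and
  marks the cell's row `failed` instead of aborting, so group n stays
  traceable.
- Seeds below 2³¹ everywhere; batch cells use `base_seed + index`.

## Validation problem sizes

The test suite and acceptance script use 100 cells for normalization
checks, 4 × 20 grids for bottom-fraction and polarity recovery, 50 cells
for the exact-oracle comparisons (Pearson direct formula, brute-force disc
loop), 20 seeds for volume recovery and coupling ordering, 1000
simulations for ANOVA calibration, and 10 cells per condition for the
demo. These sizes give stable means (binomial/SEM noise well inside each
tolerance) while keeping a full run in the tens of seconds on one CPU.

## Known limitations

- Measured ER volume is threshold-limited: when the requested bottom
  fraction is far above the support's natural share, the exponential
  weighting dims the apical reticulum below the Otsu threshold and volume
  is under-recovered (visible at bottom fractions ≳ 0.5 on the solid
  default support). The volume-recovery guarantee applies at realistic
  enrichment; the demo presets avoid the regime by building enrichment
  geometrically.
- The Pearson ROI uses the full 3-D cell mask restricted to the slab;
  whether the original interactive analyses used one 2-D ROI for all
  slices is unknowable from the outside.
- Pooled per-cell statistics ignore experiment-level clustering.
- One stack = one cropped cell; there is no multi-cell instance
  segmentation.
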