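# isquant

Quantification of endoplasmic-reticulum (ER) remodeling at the B-cell
immune synapse from multi-channel 3-D confocal stacks.

When a B cell recognizes antigen tethered to a surface, it forms an immune
synapse (IS): the cell spreads, repositions its microtubule-organizing
center (MTOC), and redistributes organelles toward the contact plane.
`isquant` implements the image statistics used to characterize how the ER
takes part in this process, for single-cell stacks with an ER marker
(e.g. VapA-mCherry or calnexin), α-tubulin and actin channels:

- **Z-scan profile** — each slice's summed fluorescence as a percentage of
  the whole-cell total, `pct_k = 100 · raw_k / Σ raw`, with the
  **synapse fraction**: the summed percentage over the first
  `⌈0.1·n_z⌉` slices closest to the coverslip.
- **Polarity index** for bead conjugates — with cell-mask centroid C,
  fluorescence centroid F, unit vector û from C to the bead and R the
  centroid-to-boundary distance along û: `PI = ((F − C)·û)/R ∈ [−1, 1]`.
- **Pearson colocalization** of two channels over the cell-mask voxels of
  the synapse slab (plain, non-thresholded r).
- **MTOC-proximal density** — mean fluorescence inside a circle of physical
  diameter (4 µm for the A20 line, 2 µm for primary B cells) on the MTOC
  slice and its two neighbors.
- **Morphometry** — ER area at the synapse plane (Otsu within the cell
  mask), actin-delimited spreading area, their ratio, and 3-D ER volume by
  26-connected components.
- **Group statistics** — one-way ANOVA with Tukey HSD (≥3 conditions) or
  Student's t-test (2 conditions), means ± SEM per condition.

Because no public raw stacks accompany this kind of experiment, the
package ships a first-class **synthetic-cell generator**
(`isquant.synthetic`) that paints hemispheroidal coverslip cells and
spherical bead conjugates with known, *measured* ground truth for every
statistic — axial ER enrichment, ER–tubulin coupling, MTOC pooling,
painted ER volume, polarization — under Poisson + Gaussian noise. All
recovery tests and the acceptance script run against that measured truth.

## Worked example

Simulate one activated cell, segment it and quantify:

```python
from isquant import generate_coverslip_cell, quantify_cell

stack, truth = generate_coverslip_cell(seed=3)
record, profile = quantify_cell(stack, "cell0")
print(f"synapse fraction  {record.metrics['is_fraction_pct']:.1f}%  "
      f"(truth {100 * truth.true_bottom_fraction:.1f}%)")
print(f"ER-tubulin r      {record.metrics['pearson_r']:.3f}")
print(f"ER volume         {record.metrics['er_volume_um3']:.1f} um3  "
      f"(painted {truth.true_object_volume_um3:.1f} um3)")
```

```
synapse fraction  24.9%  (truth 25.0%)
ER-tubulin r      0.132
ER volume         73.1 um3  (painted 74.8 um3)
```

The four-condition phenotype demo (resting, activated on glass, on 13 kPa
and on 0.3 kPa polyacrylamide gels; 10 cells per condition) reproduces the
stiffness-graded redistribution — more ER at the synapse, more ER around
the MTOC, larger ER and spreading areas, and lower ER–tubulin correlation
on stiffer substrates, with ER volume and whole-cell fluorescence
unchanged:

```bash
isquant demo --seed 0 --n-cells 10
```

```
                 is_fraction_pct     pearson_r  mtoc_density  er_volume_um3
resting             24.9 ± 0.022   0.153 ± 0.012     84 ± 3.5    31.4 ± 0.92
activated-0.3kPa    27.9 ± 0.012   0.161 ± 0.014   91.2 ± 5.2     32.3 ± 1.8
activated-13kPa     32.7 ± 0.019  0.104 ± 0.0085    109 ± 2.9    31.5 ± 0.73
activated-glass     35.6 ± 0.022   0.0869 ± 0.01      124 ± 4    29.9 ± 0.38
...
  [PASS] is_fraction_pct: glass > resting (significant)
  [PASS] pearson_r: glass < resting (significant)
  ... (10/10 ordering checks)
```

The CLI also provides `isquant generate` (write a synthetic suite as TIFF +
ground-truth JSON + manifest), `isquant quantify` (batch-process a manifest
or synthetic suite from a YAML config into per-cell CSVs) and
`isquant stats` (between-condition comparisons on a records CSV).

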