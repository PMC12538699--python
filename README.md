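# topoqc

Quality control and curation pipeline for TopoChip high-content imaging
screens.

A TopoChip presents 2176 micro-topography designs, each duplicated, plus 4
flat control units on a 66 × 66 grid of walled squares (TopoUnits). Cells —
in the reference screen, kidney podocytes stained with DAPI, phalloidin and
an anti-nephrin antibody — are cultured on the chip, imaged as stitched
z-stacks, segmented per cell, and profiled morphologically. Between raw
images and a curated single-cell database sits a stack of bookkeeping and
statistics that this package implements as tested, reusable code:

* **Grid and naming** — the chip layout (design-to-position map, flat
  orientation landmark) and the bit-exact tile filename grammar
  `[Channel]_[ChipID]_Col##_Row##_Seq####_[Stain].tif`.
* **Image-plane operations** — max/average z-projection, landmark-based chip
  orientation, bilinear tilt maps from corner focus heights, and lossless
  cropping of a stitched chip into 4356 named unit tiles.
* **Derived features** — form factor `4πA/P²`, nucleus-to-cytoplasm area
  ratio `NtoC = A_nuc / (A_cell − A_nuc)`, peripheral actin fraction, per-unit
  aggregation, and CV-vs-cell-count curves.
* **Three-tier QC with ledger accounting** — object-level exclusion rules
  (nucleus diameter 15–65 px, border/wall contact with the secondary→primary
  linkage rule); unit-level cell-count filtering (IQR bounds or the 11–64
  stability band, derivable from CV curves); and the 2.5th/97.5th-percentile
  NtoC filter. Every tier's image/object removals chain through a
  conservation-checked ledger.
* **Replicate consistency** — the k-sample Anderson–Darling test
  (Scholz–Stephens, midrank ties) plus a signal-to-noise filter: a design is
  kept only if its replicate units share one distribution (p > 0.05) and
  show 2 < |mean|/SD < 20.
* **Ranking and splitting** — top/bottom-N binarization of a readout and the
  nested stratified 80/16/4 train/test/validation split, with z-scored
  descriptor matrices for an external gradient-boosting stage.
* **Synthetic screens** — a generator that emulates the screen's statistical
  structure (two chip density classes at 39 ± 13 and 15 ± 11 cells/unit,
  nuclear area N(737, 161²) with unit-mean SD 65, feature correlations
  r = 0.83 and r = −0.87) and plants artifacts with a ground-truth registry,
  so every stage is testable offline.

## Worked example

```python
import math
from topoqc import form_factor, nto_c, build_ledger

# shape circularity: 1.0 for a circle, pi/4 for a square
form_factor(math.pi * 10**2, 2 * math.pi * 10)   # -> 1.0
form_factor(9.0, 12.0)                           # -> 0.7853981633974483

# nucleus-to-cytoplasm ratio: 1 when the areas are equal
nto_c(100.0, 200.0)                              # -> 1.0
nto_c(50.0, 550.0)                               # -> 0.1

# the screen's unit-level curation, as a conservation-checked ledger
ledger = build_ledger(
    [("count_band[11,64]", 5278, 63789),
     ("ntoc_percentile[2.5,97.5]", 2006, 27804)],
    images_in=39204, objects_in=1213838)
print(ledger.to_text())
```

prints

```
QC ledger: 39204 images, 1213838 objects in
  - count_band[11,64]: removed 5278 images / 63789 objects -> 33926 / 1150049 remain
  - ntoc_percentile[2.5,97.5]: removed 2006 images / 27804 objects -> 31920 / 1122245 remain
retained: 31920 images, 1122245 objects
```

i.e. starting from 39,204 unit images holding 1,213,838 segmented cells, the
count-stability band and the NtoC percentile filter together remove 7,284
images and 91,593 cells, leaving the curated 31,920-image / 1,122,245-cell
database.

The full pipeline (synthesize → object QC → count filter → NtoC filter →
replicate filter → rank/split) runs from the shell:

```sh
topoqc run --seed 1 --out runs/demo
```

and writes tables, removal logs, the ledger, a replicate-consistency report
and splits into the run directory.

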