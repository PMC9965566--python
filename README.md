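# mvdquant

Quantification of peripapillary choriocapillaris **microvascular dropout
(MvD)** from en-face OCT angiography, for two-group myopia cohort studies.

In en-face OCTA of the region around the optic disc, the choriocapillaris
is a bright speckled flow signal; focal loss of perfusion appears as a
contiguous dark patch (a *flow void* or MvD), almost always inside the
peripapillary atrophy (PPA) zones — the β-zone adjacent to the disc and
the α-zone peripheral to it.  `mvdquant` implements the measurement chain
used to study these lesions in myopia:

1. **Large-vessel exclusion** — bright elongated structures
   (grey ≥ 180, skeleton ≥ 30 px, width ≥ 4 px) are invalidated.
2. **Dropout detection** — connected components of valid pixels with
   grey value **< 50** and area **> 20 pixels** (both strict), restricted
   to the PPA zones, 8-connectivity; each region assigned to its majority
   zone.
3. **Zone metrics** — areas by pixel counting at the physical pitch
   (11.25 μm for a 4.5 × 4.5 mm scan of 400 clusters: one pixel is
   126.5625 μm²), dropout totals per zone, flow density
   (valid zone pixels with grey ≥ 50), and per-eye dropout presence.
4. **Cohort statistics** — quality-control filtering (score ≥ 6/10, no
   artifact flags), grouping on spherical equivalent (high myopia
   SE ≤ −6.0 D vs mild-to-moderate −6.0 < SE ≤ −0.5 D), Student t-tests,
   Spearman correlations, dropout prevalence, and the dropout-area model
   as per-predictor simple fits (signed Pearson r for age, SE, AL, β-zone
   area) plus a joint OLS fit.

Because clinical OCTA data cannot be redistributed, the package ships a
**calibrated synthetic-cohort generator**: rendered angiograms
(speckle background, vessel trees, disc, PPA rings, planted dark blobs
with exact pixel-level ground truth) together with covariates whose
group means, dropout prevalence and dropout-area correlations match the
published cohort structure the generator emulates.  Every pipeline stage
is tested against this ground truth; see `docs/methods.md` for the model,
its calibration, and what it does and does not emulate.

## Worked example

Simulate both packaged cohorts (95 high-myopia + 110 mild-to-moderate
eyes), run detection on every eye, and summarize:

```sh
mvdquant all --seed 1 --out runs/demo
```

which logs

```
all: simulated 95 eyes of 'high_myopia'
all: simulated 110 eyes of 'mild_moderate'
all: 205 eyes pooled -> runs/demo/summary.json
```

and writes per-eye images/masks, `metrics.csv` per cohort, and a pooled
`summary.json`.  For this seed the summary contains (values printed by
the run above):

| quantity | high myopia (n=95) | mild–moderate (n=110) |
|---|---|---|
| MvD area in PPA-β (mm²) | 0.248 ± 0.111 | 0.092 ± 0.142 |
| PPA-β zone area (mm²)   | 1.221 ± 0.201 | 0.560 ± 0.353 |
| SE (D) / AL (mm)        | −7.14 / 26.65 | −2.51 / 24.36 |

Pooled over 205 eyes: dropout prevalence 95.1%; simple-fit correlations
of dropout area r = 0.901 with β-zone area, r = −0.460 with SE and
r = 0.459 with AL (all p < 10⁻¹¹); the group difference in dropout area
is t = 8.7, p ≈ 10⁻¹⁵.  Highly myopic synthetic eyes thus carry roughly
three times the dropout area of mildly myopic ones, and dropout grows
with axial elongation and β-zone atrophy — the structure the generator
is calibrated to emulate.

Single-eye use:

```sh
mvdquant detect --image eye.png --disc disc.png --alpha alpha.png \
    --beta beta.png --out regions.csv --vessel-mask-out vessels.png
```

emits one row per detected region (`region_id, zone, area_px, area_mm2,
centroid_row, centroid_col, min_grey, mean_grey`).  All thresholds are
flags or YAML config (`--grey-threshold`, `--min-area`, `--connectivity`,
`--pixel-pitch-um`).

From Python:

```python
from mvdquant import read_image, read_zoneset, detect_mvd, summarize_eye
from mvdquant.pipeline import analyze_eye

image = read_image("eye.png")                      # 8-bit grayscale PNG
zones = read_zoneset("disc.png", "alpha.png", "beta.png", image)
regions, metrics, vessels = analyze_eye(image, zones)
print(metrics.mvd_total_area_beta_mm2, metrics.mvd_present)
```

## Layout

```
src/mvdquant/
  io.py         images, masks, manifests, config (format contracts)
  vessels.py    large-vessel segmentation and exclusion
  detection.py  the dark-region / connected-component detector
  metrics.py    per-eye areas, densities, presence
  cohort.py     QC, grouping, t-tests, correlations, regression
  synthetic.py  calibrated cohort generator (profiles/*.yaml)
  pipeline.py   end-to-end helpers
  cli.py        `mvdquant` subcommands: simulate/detect/metrics/cohort/all
docs/methods.md the model, calibration and limitations
tests/          unit, property and end-to-end suites
```
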