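# nucleoquant

Quantitative nucleolar-prominence histology in synthetic form: the package
generates seeded H&E-like tiles and patient cohorts with known ground truth,
segments nuclei as star-convex polygons with IoU non-maximum suppression,
grades every cell by a deterministic nucleolar-prominence rule, profiles
regions of interest as G3/Other cell densities per mm², derives
grade-discriminating thresholds (ROC/AUC, Youden's J, one-way ANOVA + Tukey
HSD), and stratifies cohorts into four prognostic density quadrants with
Kaplan–Meier curves, the k-sample log-rank (Mantel–Cox) test and Fisher's
exact test.

## Layout

| module | what it does |
|---|---|
| `nucleoquant.synthdata` | seeded tile / tissue-pattern / cohort generators with ground truth |
| `nucleoquant.segment` | probability + radial-distance maps, polygon candidates, NMS, rasterization |
| `nucleoquant.classify` | rule-based cell grading (G1/G2/G3/Other) and the binary G3-vs-Other task |
| `nucleoquant.metrics` | square ROIs, densities per mm², %G3 profiles |
| `nucleoquant.gradestats` | ROC/AUC, Youden cutpoint, ANOVA + Tukey, boxplot summaries |
| `nucleoquant.survival` | quadrant assignment, Kaplan–Meier, log-rank, Fisher exact, cohort report |
| `nucleoquant.io` / `pipeline` / `cli` | CSV/GeoJSON/TIFF readers-writers, seeded end-to-end driver, CLI |

## CLI

Every stage is a subcommand of `nucleoquant` (see `--help` on each):

```bash
nucleoquant simulate --kind tile --seed 1 --n-cells 800 --out scratch/tile
nucleoquant segment --input scratch/tile.png --out scratch/pred.tiff --geojson scratch/cells.geojson
nucleoquant classify --tile scratch/tile.png --mask scratch/pred.tiff --out scratch/cells.csv
nucleoquant profile --cells scratch/cells.csv --roi-perimeter 4000 --out scratch/profile.csv
nucleoquant grade --profiles scratch/profiles.csv --out scratch/grade_report.json
nucleoquant simulate --kind cohort --seed 2 --out scratch/cohort.csv
nucleoquant survive --cohort scratch/cohort.csv --cut-g3 533 --cut-other 4133 --out scratch/survival.json
nucleoquant pipeline --seed 1 --out scratch/run1   # full chain + checksum manifest
```

GeoJSON output follows the QuPath dialect (FeatureCollection of polygons in
pixel coordinates with `classification`/`measurements` properties) so
segmentations and class overlays can be inspected in a viewer.

## Conventions

- Coordinates: 0-based pixels, x = column, y = row; µm = px × pixel size.
- Ray k of a star-convex polygon points at angle 2πk/n_rays (angle 0 = +x,
  toward +y in image convention).
- Quadrants use a uniform strict-greater positivity rule at the density
  cut-offs (defaults 533 G3 and 4133 Other cells/mm²).
- Every generator and simulation takes an explicit integer seed;
  identical seeds give bit-identical artifacts (checksummed by
  `pipeline.run_pipeline`).
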