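# peritomorph

Automated quantitative histomorphometry of the peritoneal membrane.

The peritoneum — the thin tissue layer lining the abdominal cavity — is the
exchange membrane used in peritoneal dialysis. Its transport capacity is set
by structures a few micrometers across: submesothelial blood and lymphatic
capillaries, their endothelial walls, and the thickness of the
submesothelial zone, all of which change strongly with age (infants have
more than twice the capillary density of school-age children). Quantifying
these structures from stained whole-slide scans requires a chain of image
analysis steps whose definitions matter as much as the segmentation itself.

`peritomorph` implements that chain for single-channel stain images:

* **stain quantification** — per-stain intensity binning
  (negative/weak/medium/strong) and *positivity*, the positive-pixel
  fraction of the analyzed tissue;
* **vessel segmentation** — connected stain-positive rings with lumina
  recovered by hole-filling; vessels without a distinct lumen are flagged
  *collapsed* (counted for density, excluded from shape metrics); blood
  counts come from intraindividual CD31 − podoplanin differencing, since
  CD31 marks all endothelium and podoplanin only lymphatics (plus the
  mesothelium, which is masked);
* **morphometry** — microvessel density (vessels/mm²), vessel/endothelial/
  lumen areas, Crofton perimeters, endothelial thickness
  (= endothelial area / mean ring length; r_out − r_in for an annulus), and
  endothelial surface area per tissue volume (Σ endoluminal perimeter /
  analyzed area — the section thickness cancels);
* **layer structure** — submesothelial thickness as the median of ≥ 5
  perpendicular transects, and clustering of vessel depths into the three
  submesothelial vessel layers (equal-weight Gaussian mixture by default);
* **reference curves** — LMS (Box–Cox lambda–mu–sigma) age-reference
  centiles: z = ((y/M)^L − 1)/(L·S) for L ≠ 0, z = ln(y/M)/S for L = 0,
  with L, M, S smooth functions of log(age + 0.25);
* **cohort statistics** — Shapiro–Wilk-driven selection of ANOVA vs
  Kruskal–Wallis, chi-square/Fisher, Pearson vs Spearman, and the
  seven-age-group assignment.

Because no public specimen set exists, the package ships a seeded
**synthetic tissue generator** (`peritomorph.synthetic_tissue`) that renders
dual-stain sections with fully known ground truth — vessel positions,
radii, wall thicknesses, layer depths, mesothelial coverage, mast cells —
so the entire pipeline is validated as a closed parameter-recovery loop:
set the generator to a published group value, run the pipeline blind,
compare. See `docs/methods.md` for the model and its limits.

## Worked example

```python
import numpy as np
from peritomorph import SectionParams, generate_section, quantify_sample

params = SectionParams(analyzed_area=0.5, seed=42)   # infant parameter set
sections, truth = generate_section(params)            # 4 channels + truth
metrics, records = quantify_sample(sections, sample_id="demo")

print(f"true blood density   : {truth.vessel_density('blood'):.1f} /mm^2")
print(f"measured blood       : {metrics.blood_density:.1f} /mm^2")
print(f"median wall thickness: {metrics.blood_endothelial_thickness:.2f} um")
print(f"submeso thickness    : {metrics.submesothelial_thickness:.0f} um")
print(f"layer depths         : {np.round(metrics.layer_depths, 1)} um")
print(f"mesothelial coverage : {metrics.mesothelial_coverage:.2f}")
print(f"mast cells           : {metrics.mast_cell_density:.1f} /mm^2")
```

prints

```
true blood density   : 241.9 /mm^2
measured blood       : 241.9 /mm^2
median wall thickness: 1.32 um
submeso thickness    : 231 um
layer depths         : [ 45.4 102.2 175. ] um
mesothelial coverage : 0.79
mast cells           : 18.0 /mm^2
```

The generator drew a Poisson realization of the infant condition (truth
241.9 vessels/mm² on this 0.5 mm² section against the 223/mm² parameter);
the pipeline recovered the blood density exactly by CD31 − podoplanin
differencing, the endothelial wall within discretization of the 1.29 μm
parameter, and the submesothelial thickness within 1 μm of the 230 μm
truth. Coverage 0.79 reflects the generated 21% denuded surface stretch;
mast cells are a small-count Poisson draw (9 cells on 0.5 mm²).

### Command line

```bash
peritomorph simulate --out runs/sim --seed 7 --n-per-group 2
peritomorph quantify --in runs/sim --out runs/quant
peritomorph reference --metrics runs/quant/sample_metrics.csv --out runs/ref
peritomorph report    --metrics runs/quant/sample_metrics.csv --out runs/rep
```

`simulate` writes per-patient TIFF channels, JSON ground truth and a cohort
CSV; `quantify` produces `sample_metrics.csv` (one row per sample) and
`vessel_records.csv` (one row per vessel); `reference` fits LMS models and
centile tables for thickness and vessel densities; `report` runs the
age-group comparisons. Every output directory carries a manifest with the
seed and a configuration hash.

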