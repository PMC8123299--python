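# pnpcyto

Digital cytometry for low-abundance cell-surface antigens: counting
antibody-conjugated plasmonic gold nanoparticles (PNPs) bound to individual
immune cells under darkfield microscopy, with simultaneous immune-lineage
assignment from multiparameter fluorescence.

## The problem

Some clinically interesting molecules — the ovarian-cancer biomarker CA125
(an epitope of the mucin MUC16) bound to circulating leukocytes via
Siglec-9 is the motivating case — sit on cell surfaces at near-single-
molecule abundance.  Fluorescent labels drown in cellular
autofluorescence and photobleach; ~80 nm gold nanoparticles scatter
resonantly, appear ~13× brighter than the cell interior under darkfield
illumination, and never bleach.  Conjugating the detection antibody to a
nanoparticle turns "measure a faint intensity" into "count bright dots".

`pnpcyto` implements the full measurement pipeline for such an instrument
(a darkfield z-stack of 40 slices at 0.5 µm plus four RGB fluorescence
frames per field of view), and — since real patient images are not
distributable — a synthetic field-of-view generator with complete ground
truth (cell contours, lineages, every nanoparticle's 3D position, event
multiplicity and scattering color, the true 12×5 spectral mixing matrix,
camera noise), so every stage is testable end to end.

## Pipeline

1. **Spectral unmixing** — bead-calibrated 12×5 mixing matrix `M`
   (4 excitation bands × RGB camera channels by 5 fluorochromes:
   BV510-CD45, BV421-CD19, AF488-CD14, PE-CD56, AF647-CD3); per-pixel
   abundances `a = M⁺ v` with the Moore-Penrose pseudoinverse.
2. **Cell finding** on the compensated CD45 plane: ¼ downscale, local
   threshold (window 351 px, offset 0.05), connected components
   (500–6000 px), circular Hough transform (radii 15–35 px), one best
   circle per component.
3. **Contour delineation** with a small U-shaped segmentation network
   (82×82 crops, 50/25/25 split, Dice loss, Adam, 150 epochs,
   best-validation checkpoint, 0.5 output threshold), area-filtered to
   16–400 µm².  Implemented in numpy/numba — no deep-learning framework
   required.
4. **Lineage gating**: positive for a fluorochrome iff inside mean >
   outside mean + 2·SD; CD45⁺ with one lineage marker names the class,
   CD56⁺CD14⁺ is NK-T, other multi-marker cells are excluded.
5. **Nanoparticle quantification**: per-slice Laplacian-of-Gaussian blob
   detection inside the contour, DBSCAN linking across slices,
   cluster-size filtering, and color classification of each 3D event —
   red/green ratio in (0,1] = single particle, (1,2] = duplet (yellow),
   >2 = triplet (red); the per-cell count sums multiplicities.
6. **Cohort statistics**: per-sample, per-subtype Poisson means
   λ = mean PNPs/cell; two-sided Mann-Whitney U between cohorts (with
   Shapiro-Wilk reported), ROC AUC = U/(n₁n₂), Pearson r² between subtypes
   and against serum values, binding stratification at 5 and 10 PNPs/cell,
   and 1.5×IQR box-plot summaries.

## Worked example

Simulate a small two-group cohort, push one sample through the pipeline
and aggregate:

```python
import pandas as pd
from pnpcyto import CompensationModel, default_mixing_matrix, RunConfig
from pnpcyto.sim import CohortSpec, simulate_cohort
from pnpcyto.pipeline import run_fov, RunStats
from pnpcyto.cohort_stats import summarize_sample

mixing = CompensationModel.from_matrix(default_mixing_matrix())
cfg = RunConfig()
cfg.optics.z_slices = 9          # test-scale stack
cfg.detect.window_px = 31        # local-threshold window for 512 px frames

spec = CohortSpec(n_samples_per_group={"patient": 1, "control": 1},
                  cells_per_sample=12, seed=7)
cohort = simulate_cohort(spec, cfg.optics)

sample = cohort.samples[0]       # a control sample
stats = RunStats()
records = []
for i in range(len(sample.cells_by_fov)):
    fov = sample.render_fov(i, mixing)
    records += run_fov(fov, mixing, cfg, sample_id=sample.sample_id,
                       fov_id=f"fov_{i:03d}", stats=stats)

cells = pd.DataFrame({"sample_id": sample.sample_id,
                      "lineage": [r.lineage for r in records],
                      "pnp_count": [r.pnp_count for r in records]})
summary = summarize_sample(cells, group=sample.group)
print(len(records), "cells;", stats.drops)
print({k: round(v, 2) for k, v in summary.lambda_by_subtype.items()})
print("truth:", dict(sample.truth.groupby("lineage")["true_count"].mean().round(2)))
```

Output:

```
12 cells; {}
{'AllPBMC': 6.08, 'T': 2.62, 'B': 4.0, 'NKT': 15.0, 'Monocyte': 32.0, 'NK': 1.0}
truth: {'B': 4.0, 'Monocyte': 33.0, 'NK': 1.0, 'NKT': 15.0, 'T': 2.5}
```

All 12 simulated cells of this control sample were detected with no drops,
and the automated per-subtype mean nanoparticle loads track the realized
ground truth (exact for B/NK/NK-T; one particle of a 33-count monocyte
missed and one spurious detection on a T cell at this tiny size).  The
all-PBMC
aggregate (6.08 PNPs/cell) is the mean over every CD45⁺ cell; the monocyte
mean sits near the control-cohort default of 27.6 PNPs/cell while T cells
sit near 1.4 — the λ table the generator draws from.

A command-line interface mirrors the library:

```bash
pnpcyto simulate --out data/ --seed 1 --samples-per-group 2
pnpcyto segment-train --out model/ --epochs 150 --seed 1
pnpcyto run --sample data/patient_00 --model model/ \
        --config data/config.yaml --out cells.tsv
pnpcyto cohort --cells cells.tsv --meta meta.tsv --out report/
```

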