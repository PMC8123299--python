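# Methods

`pnpcyto` reimplements an automated "digital cytometry" measurement: counting
antibody-conjugated ~80 nm gold plasmonic nanoparticles (PNPs) bound to
individual peripheral-blood mononuclear cells (PBMC) from darkfield z-stacks,
while assigning each cell an immune lineage from four-band multiparameter
fluorescence, and comparing per-lineage nanoparticle loads between a patient
and a control cohort.  Because the patient images behind the original
measurements are not published, the package pairs the analysis pipeline with
a synthetic field-of-view generator carrying complete ground truth; every
stage is validated against that ground truth at desk scale.

## Acquisition model (simulator)

One field of view consists of

* a darkfield z-stack: `z_slices` RGB frames spaced `z_step_um` apart and
  centred on the cells' equatorial plane (production geometry: 40 slices at
  0.5 µm, spanning [-10, +9.5] µm — the stack is defined as
  `(arange(z) - z//2) * step`, so a "±10 µm" sweep at 0.5 µm emits exactly 40
  planes);
* four RGB fluorescence frames, one per excitation band of a four-band
  (Pinkel) filter set.

Default object-space sampling is 0.0548 µm per full-resolution pixel (a
3.45 µm camera pixel behind 63× magnification).  Test-scale frames default
to 512×512 px rather than the production 4096×2678 camera; all geometry is
configurable through `OpticsConfig`.

The optical model is phenomenological:

* **Cells** are slightly jittered disks (radius default 3.3–4.8 µm, the
  lymphocyte/monocyte range at the small end) with lognormal speckle texture
  inside the contour (σ = 0.25, lateral correlation 2 px) — darkfield cell
  interiors are granular, and the detector has to be robust to texture.
  Texture is drawn independently per slice.
* **Nanoparticle events** render as lateral Gaussian spots (σ = 2 px) whose
  peak luminance is `pnp_to_background_ratio` (default 13) times the mean
  interior luminance, attenuated as a Gaussian in axial distance and visible
  within ±2 µm of their true z.  With noise and texture disabled the peak
  equals 13× the interior exactly; this is asserted in the tests.
* **Multiplets.** Particle pairs closer than the diffraction limit appear as
  a single spot whose plasmon resonance is red-shifted; that is precisely
  what the green/yellow/red color classes measure.  The generator therefore
  splits a cell's particle count into singlet/duplet/triplet *events*
  (weights 0.60/0.25/0.15) and draws each event's red/green ratio uniformly
  from its class interval — (0, 1] singlet, (1, 2] duplet, (2, 3] triplet —
  mirroring the classifier's decision regions so ground truth is recoverable.
  Resolvable events keep a minimum lateral separation (default 0.66 µm,
  about twice the diffraction limit); unresolvable pairs are *generated as*
  multiplets rather than as colliding singlets.
* **Fluorescence** is the linear model `v = M·a + noise` per pixel, where
  `M` is the 12×5 mixing matrix (4 bands × RGB by 5 fluorochromes) and `a`
  the per-fluorochrome abundance vector.  Leukocytes express CD45 plus
  exactly their lineage-defining markers (CD3 T, CD19 B, CD56 NK, CD14
  monocyte, CD56+CD14 for the NK-T class as the protocol defines it), with
  lognormal per-marker brightness jitter (σ = 0.15).
* **Camera noise** is Gaussian read noise (SD 2 counts) plus a Gaussian
  approximation of shot noise; both are drawn in a single pass with variance
  `read² + max(signal, 0)`.  Intensities are in arbitrary camera units — the
  platform's absolute exposure scale is not part of the model.

Per-cell particle counts are Poisson with lineage- and cohort-dependent
means; the default λ table is the study-level set of cohort averages
(patients: NK 2.86, T 4.36, monocytes 27.71, B 10.45, NK-T 9.10; controls:
NK 1.11, T 1.38, monocytes 27.58, B 5.19, NK-T 10.03), and the default
lineage mixture (T 0.70, B 0.10, NK-T 0.06, monocytes 0.08, NK 0.06)
matches a healthy PBMC flow-cytometry composition.

What the simulator deliberately does **not** model: physical Mie scattering
(brightness is phenomenological), autofocus/stage behaviour, photobleaching
(gold nanoparticles do not bleach), z-correlated interior texture, real
contour irregularity beyond mild ellipticity, autofluorescence spectra, and
nanoparticle internalization by monocytes.  Passing tests therefore
demonstrate the correctness and calibration of the *algorithms* under a
controlled optical model, not clinical performance on patient material.

## Pipeline

1. **Color compensation.**  Bead slides (one per fluorochrome) are
   thresholded with Otsu on the maximum over the 12 channels; components
   smaller than 5 px are rejected as specks, and fewer than 7 beads is a
   calibration error.  Column *j* of `M` is the per-channel median over the
   pooled bead pixels of slide *j* (pooling chosen over per-bead medians for
   robustness; configurable), after subtracting the per-channel median of
   the non-bead background (camera offset).  `M⁺ = pinv(M)` unmixes every
   pixel; a condition check rejects spectrally degenerate panels.  Columns
   are not normalized, so abundances are fractions of bead-median
   brightness.  Negative abundances are retained so downstream statistics
   see unbiased noise.
2. **Cell finding** runs on the compensated CD45 plane: 4×4 local-mean
   downscaling; local-mean threshold (window 351 px, offset 0.05 on the
   image normalized to [0, 1] by its maximum — the window must exceed the
   cell diameter, which the production window comfortably does);
   8-connected components kept at 500–6000 downscaled px (inclusive); per
   component, a circular Hough transform over radii 15–35 px (read as
   *downscaled* pixels; full-resolution radii would imply implausibly small
   cells) on the component's edge map.  The highest-scoring circle whose
   center lies inside the component bounding box is the one candidate;
   ties break toward the smaller radius, then scanline order.
3. **Contour delineation.**  82×82 crops of the downscaled CD45 plane
   (reflect-padded at borders), min-max normalized, segmented by a small
   encoder-decoder network; output thresholded at 0.5; the foreground
   region containing (or nearest to) the crop center is the mask; masks
   outside 16–400 µm² are rejected.  A `--no-unet` fallback uses the Hough
   circle itself as the contour for runs that do not need trained weights.
4. **Lineage.**  A cell is positive for a fluorochrome when its mean
   compensated signal inside the contour exceeds the outside mean plus 2
   outside SDs (ties negative).  "Outside" is the Euclidean ring 5–15 px
   from the contour, excluding neighbouring masks, with a whole-image
   fallback in crowded fields.  CD45⁻ → not a leukocyte; CD45⁺ with exactly
   one lineage marker → that class; CD56⁺CD14⁺ → NK-T (kept verbatim from
   the measurement protocol even though NK-T cells are canonically
   CD3⁺CD56⁺; `LineageConfig.nkt_pair` switches the pairing); any other
   multi-marker pattern, and CD45⁺ cells with no lineage marker, are
   excluded from subtyping but still count toward whole-PBMC aggregates.
5. **Nanoparticle quantification.**  Per slice, scale-normalized
   Laplacian-of-Gaussian responses (σ ∈ {2, 3, 4} px, maximum over scales;
   the Laplacian is strictly in-plane) are thresholded at 8× the median
   absolute deviation of the response inside the cell contour; local maxima
   inside the contour become 2D detections.  DBSCAN (min_samples = 1,
   eps = 5 px) links them into 3D events on (x, y, z_index·2 px): the axial
   spacing in the clustering metric is *compressed* relative to physical
   anisotropy, because one particle's footprints overlap laterally on
   consecutive slices while distinct particles are laterally separated —
   scaling z by the physical anisotropy (≈9 px per slice) would place
   consecutive-slice members of the same particle out of reach of eps.
   Clusters with fewer than 3 or more than 25 members are discarded; the
   member at the (lower) median slice is the event coordinate.  The event's
   red/green ratio over a 3×3 neighborhood classifies it green/yellow/red →
   multiplicity 1/2/3, half-open boundaries ((0,1], (1,2], (2,∞)).  By
   default the per-channel slice median inside the contour is subtracted
   before the ratio: the cell interior scatters broadband (ratio ≈ 1) light
   that otherwise dilutes the spot color toward 1 and systematically demotes
   triplets near the ratio-2 boundary; `PnpConfig(background_subtract=False)`
   restores the raw division.  The per-cell count is the sum of
   multiplicities (`count_mode="events"` counts events instead).
6. **Aggregation and statistics.**  Within a sample, per-subtype counts are
   summarized by their arithmetic mean — the λ of the assumed Poisson
   distribution — plus an all-PBMC aggregate over every CD45⁺ cell, and
   binding stratification at cutoffs 5 and 10 (low < 5 ≤ medium < 10 ≤
   high).  Cohorts are compared per subtype with the two-sided Mann-Whitney
   U test (exact enumeration when both groups have ≤ 20 tie-free samples,
   normal approximation with tie correction otherwise; Shapiro-Wilk p is
   reported alongside, not used as a gate).  The rank rule "higher λ ⇒
   patient" has ROC AUC = U/(n₁n₂), ties counted half.  Associations use
   Pearson r² with pairwise deletion of missing subtypes; serum values are
   an optional per-sample metadata column.  Box-plot summaries flag
   outliers beyond 1.5 interquartile ranges from the quartiles.  No
   multiple-testing correction is applied.

## The segmentation network

No deep-learning framework is assumed: the network is a small
encoder-decoder ("U"-shaped) model implemented directly over numpy with
single-threaded numba kernels for the 3×3 convolutions (a pure-numpy GEMM
path computes the same map and cross-checks the kernels in the tests; all
gradients are verified against adjoint identities and finite differences).
The default architecture has 3 resolution levels with 4/8/16 channels, two
3×3 convolutions per block, max-pool downsampling, nearest-neighbor
upsampling with skip concatenation, and a 1×1 sigmoid head (~7.5k
parameters) — sized so that the full 150-epoch protocol trains on one CPU
core in a few minutes.  The segmentation task (one bright textured cell per
crop, occasionally a partial neighbor) does not reward more capacity: the
held-out Dice exceeds the 0.971 gate with margin at this size.

Training follows the measurement protocol exactly: one fixed 50/25/25
train/validation/test split; soft-Dice loss (smoothing constant 1.0); Adam
("adaptive momentum"), learning rate 1e-3; 150 epochs with no early
stopping; per-epoch hard-Dice validation; the best-validation checkpoint is
kept.  Batch size is 8 (keeps the convolution working set in cache on one
core).  No augmentation is used.  Training, splitting and initialization
derive from a single seed and are bit-reproducible.

## Numerical and design choices

* Downscaling is 4×4 local-mean pooling (anti-aliased).
* The local-threshold offset 0.05 applies after normalizing the downscaled
  image to [0, 1] by its maximum (the protocol states no scale).
* Hough tie-breaks: smaller radius first, then scanline order.
* Even-sized clusters take the lower-median slice as the central member.
* Gradients and Adam state flush magnitudes below 1e-30 to zero: such
  values are numerically irrelevant but would drive float32 arithmetic into
  the subnormal range, where late-training epochs slow down severalfold on
  CPUs.
* A ratio that is non-positive after background subtraction counts as green
  (a background fluctuation, not a red-shifted spot); a non-positive green
  channel maps to red (infinite ratio) and is logged.
* Degenerate inputs: blank/constant crops are dropped with a logged reason;
  empty outside rings fall back to whole-image background; an all-identical
  Mann-Whitney comparison returns U = n₁n₂/2, p = 1 with a warning;
  constant vectors yield missing correlations, zero-cell subtypes yield
  missing λ (never 0).
* Event conservation: every Hough candidate ends as a kept cell or a
  logged drop, and `n_candidates = n_cells + Σ drops` is asserted in tests.

## Validation experiments and problem sizes

`pnpcyto.validation` holds the canonical experiments; the test suite and
`scripts/acceptance.py` call the same code.

* **Segmentation quality**: 400 simulated annotated crops, full 150-epoch
  protocol, held-out test Dice ≥ 0.971 (typically ≈ 0.98 at these sizes).
* **Counting accuracy**: 98 single-cell 40-slice stacks — 49 with
  Poisson(4) loads (randomly sampled binding) and 49 drawn uniformly from
  10–30 particles (medium/high binders oversampled, mirroring the
  validation design that avoids a low-count-dominated sample); automated
  vs true counts must reach r² ≥ 0.752 and mean absolute error
  ≤ 2.72 particles/cell.
* **λ recovery**: for λ ∈ {0.5, 2, 5, 10}, single-cell fields (9-slice
  stacks) run through the full pipeline (compensation → detection →
  Hough-circle contour → quantification); the mean automated count must
  sit within 2% of the realized ground-truth mean of the same cells.
  Comparing against the *realized* rather than nominal mean isolates the
  pipeline's counting bias from the generator's Poisson sampling noise.
  Sample sizes are 1000/600/500/400 cells, chosen so the Monte-Carlo
  standard error of the bias estimate stays well inside the 2% band.
* **Detection accuracy**: 20 fluorescence fields of 4 non-overlapping
  cells; recall and precision ≥ 0.95 with full candidate accounting.

## Known limitations

* The simulator's cells are near-circular; real degraded or touching cells
  are harder, and the published contour-quality figure on manual
  annotations is matched here only on synthetic annotations.
* Monocyte-sized cells (up to ~10 µm radius) are under-represented by the
  default radius range; the range is configurable but the Hough radius band
  (15–35 downscaled px) bounds what the detector accepts, as in the
  original protocol.
* The color-multiplicity map saturates at triplets; events of four or more
  particles are counted as 3.
* Absolute intensities are arbitrary; only ratios and contrasts matter
  anywhere in the pipeline.
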