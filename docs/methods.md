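# Methods

This note documents the models, parameters and design decisions behind
`nodemorph`, and what the synthetic benchmark does and does not show.

## Synthetic slide model

A slide is a white background (RGB ≈ 247) carrying `n_sections`
elliptical tissue sections placed by rejection sampling (bounded
retries; impossible configurations raise a placement error naming the
constraint). Each section consists of, from outside in:

* a **capsule** rind (default 3 px) in an eosinophilic pink — kept
  foreground-dark so that Otsu-based detection traces the true outer
  boundary even though the sinus beneath it is pale;
* a **subcapsular sinus band** whose width is drawn per section from
  `scs_width_px` (default 4–7 px, i.e. 16–28 µm at the default
  4 µm/px);
* branching **intranodal sinus channels**: random trees of thick
  polylines grown inward from the SCS, added until the per-section
  sinus fraction reaches `sinus_fraction` (default 0.12, emulating
  reported normalised sinus areas around 0.14);
* 0–20 **germinal-centre ellipses** (default radii 8–20 px ≈ 60–160 µm
  diameter) placed inside the tissue interior with margins that keep
  them disjoint from each other and from the sinus system.

Colours are flat class colours plus a low-frequency intensity field and
per-pixel Gaussian noise. The sinus colour (luminance ≈ 193) is pale
relative to tissue (≈ 150) but well below background (≈ 246), as in
H&E, so thresholding keeps sinuses inside the tissue class.

Ground truth is analytic: section contours are the ellipse polygons;
per-section GC count, mean area (πab·mpp²) and mean circularity
(isoperimetric ratio with Ramanujan's perimeter) come from the planted
parameters; sinus area is the constructed mask's pixel count; the
planted SCS width is exact at the four axis crossings because the band
is generated by axis-shrinkage of the section ellipse.

**What the generator does not emulate:** nuclear texture, stain
physics and variation, scanner artefacts, touching or occluded
follicles, necrosis, and metastatic tissue. Passing tests therefore
demonstrate that the *mechanisms* (thresholding, tiling, training,
stitching, measurement, statistics) are correct — not that the shipped
tiny models would segment clinical H&E.

## Cohort model

Per patient, lymph-node feature records are drawn from distributions
matched to reported per-LN statistics (GC count ~ Poisson(2), mean GC
area lognormal around 0.055 mm², circularity ≈ 0.75 ± 0.08, normalised
sinus area Beta(2,12), SCS width lognormal around 20 µm), or resampled
from slide ground truth. The named feature is averaged across the
patient's LNs; patients above the effect cut-off (default: mean GC
count ≥ 2) have hazard `baseline × HR` (defaults 0.01/month × 0.3),
with independent exponential censoring (0.005/month, ≈ 25–30%
censored at n = 400). The exponential baseline makes proportional
hazards exact, so Cox regression is an unbiased estimator of the
planted log-HR and confidence-interval coverage is a clean acceptance
property.

## Section detection

Luminance 0.299R + 0.587G + 0.114B; Otsu's threshold computed by
exhaustive between-class-variance maximisation over integer thresholds
0–255 (deterministic; constant rasters raise). Foreground is the dark
class; morphological closing then opening with a 5 px disk removes
speckle and bridges thin pale bands; holes are filled; external
contours are traced at sub-pixel level (marching squares), rescaled to
finest-level coordinates, filtered at `min_area_mm2` (default 0.5 mm²)
and returned in reading order. Detection runs at the coarsest pyramid
level under 4 megapixels; contour areas are level-invariant to ~1%.

## Segmentation models

All variants are symmetric encoder–decoder FCNs with skip connections,
built on a NumPy engine (im2col convolution with dilation, 2×2 max
pooling, nearest-neighbour upsampling, Adam). Gradients are
hand-derived and verified against central differences in the test
suite (the finite-difference check randomises biases first; a ReLU
whose pre-activation is exactly zero otherwise produces a spurious
kink mismatch).

* `unet`: double 3×3 conv blocks; depth = number of encoder blocks
  (5 in the full-scale configuration; the desk-scale benchmark uses 3).
* `atten_unet`: additive attention gates on every skip connection.
* `ms_unet`: encoder blocks replace each convolution with parallel
  atrous branches at rates (1, 2, 4), concatenated and fused 1×1, so a
  single pass combines receptive fields equivalent to ×10/×5/×2.5
  views. The pyramid-of-inputs alternative was rejected in favour of
  atrous branches: one forward pass, one coordinate frame.

Two independent binary models (GC, sinus) are trained rather than one
three-class model, mirroring separate annotation passes per structure.
Loss is BCE + soft Dice with equal weights (exposed in config);
optimiser Adam at 1e-3 (benchmark 3e-3), batch 8. Tiles default to
256 px with 50% overlap at full scale; the benchmark uses 64 px tiles
with 32 px overlap, capped at 12 tiles per section with
foreground-containing tiles preferred (class balance at small step
counts). Splits are at section level — no section contributes tiles to
two partitions — and a single seed drives initialisation, shuffling and
augmentation, making training bit-reproducible.

### Benchmark problem sizes

The segmentation benchmark uses 12 single-section slides (~340 px),
split 8/2/2, ten epochs — a few minutes per model on one CPU core.
Held-out Dice ≥ 0.70 for both structures is the mechanism criterion;
the tiny models reach ≈ 0.96 (GC) and ≈ 0.81–0.92 (sinus).

### Multiscale-vs-single-scale comparison

The variant comparison uses a benchmark flavour in which follicles span
4–26 px radius and share one pale colour with sinuses, so intensity
cannot separate them — only shape and context can. Both variants run
at depth 2 and equal width/schedule: there a plain 3×3 encoder's
receptive field (~15 px) is smaller than the largest follicles
(~55 px diameter) while the atrous branches reach ~50 px, so the
comparison isolates multi-scale context rather than raw capacity. The
score is the best validation Dice over the schedule. At depth 3 the
single-scale receptive field already covers the 64 px tile and the two
variants are statistically indistinguishable on this task — the
comparison is a directional mechanism check, not a claim about
clinical imagery.

## Inference and stitching

Tiles are laid on a grid with the configured overlap (a final offset
tile guarantees full coverage); overlapping probabilities are averaged
arithmetically (seam-free and exactly consistent with a single pass for
padding-insensitive models); sections smaller than a tile are
reflect-padded and the padding discarded before aggregation. The
stitched probability raster is clipped to the section contour and
thresholded at 0.5 (configurable).

## Morphometrics

GC instances are 8-connected components with holes filled, kept when
the centroid lies inside the LN contour and the traced-contour area is
≥ `min_area_um2` (default 2,000 µm², ≈ a 50 µm follicle). Area and
perimeter come from the sub-pixel marching-squares contour; the
perimeter is measured after simplifying the polygon at 0.8 px
tolerance, which removes the rasterisation staircase that otherwise
inflates perimeters ~5% on disks (and circularity ~10%). Circularity
is 4πA/P²: 1.00 ± 0.05 for a rasterised disk, π/4 for a square.

Sinus area is the in-contour sinus pixel count × mpp²; it is reported
both raw (mm²) and normalised by LN area (dimensionless), and the
dichotomization preset accepts either — the published cut-off of 0.13
is labelled mm² in one table but defined as a normalised ratio in the
text, so both quantities are exposed rather than guessing.

The SCS width heuristic operationalises a calliper protocol: the
longest chord of the contour (convex-hull antipodal pair) defines the
major axis, an orthogonal axis runs through the centroid, and at each
of the four boundary crossings the width is the longest consecutive
run of sinus pixels along the inward ray within a 200 µm capsule band,
scanning ±5° if the exact ray misses; missing crossings contribute 0
with a flag. On masks where an intranodal channel joins the SCS at a
crossing the run extends inward and overestimates that crossing — the
averaging over four points damps this, and the clean-annulus oracle
(15 px band → 15 ± 1 µm) pins the un-confounded behaviour.

GC-count F1 uses greedy one-to-one matching by descending IoU with
threshold 0.5; empty-versus-nonempty sets score 0 by convention.

## Concordance

Dice of two empty masks is defined as 1 (perfect agreement on absence)
and flagged so cohort means can exclude such LNs. Pairwise agreement
averages over annotator pairs within each LN, then across LNs, with
the standard error taken across LNs — the alternative (pooling pixels)
weights large LNs more and is not what a per-case reading study
reports. Polygons rasterise with vertices at pixel centres (even-odd
fill) at the finest shared frame.

## Outcome analysis

Kaplan–Meier and Cox fits delegate to lifelines; model significance is
the likelihood-ratio test against the null model, covariate p values
are Wald. The minimal-p cut-point scan evaluates every unique observed
value keeping both groups ≥ 10% of the cohort (the constraint is a
design default; it is not taken from any published protocol) and uses
a vectorised log-rank implementation (verified against lifelines to
1e-10) because a model-fit call per candidate cut would dominate run
time. The scan's anti-conservatism is quantified, not hidden: on null
data (n = 400) the median minimal p across replicates falls below
0.05. Rank tests use mid-ranks with the exact Mann–Whitney
distribution for small tie-free samples and the normal approximation
otherwise; identical Kruskal–Wallis samples return p = 1 by
convention. Patients with no lymph node in the requested involvement
subset are excluded (NaN), not imputed. Endpoint names (DMFS, DRFS)
are labels only; the analysis is endpoint-agnostic.

## Numerical and degenerate-input conventions

* Rasters are (row, col), 0-based; polygons are (x = col, y = row)
  vertex lists; bounding boxes are half-open.
* Max-pool gradient ties route to the first maximum; upsampling is
  nearest-neighbour; convolutions use zero 'same' padding.
* Binarisation is `p ≥ t`; both-empty Dice = 1; F1 with zero true
  positives = 0; blank slides detect zero sections without error;
  constant rasters have no Otsu threshold and raise.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; two runs with equal seeds produce
  bit-identical slides, splits, weights and cohorts.

## Known limitations

The bundled models are desk-scale: they demonstrate the training and
inference mechanics on synthetic imagery and make no claim on clinical
slides. The SCS measurement inherits the mask-level ambiguity noted
above. The generator's sinus fraction is controlled to ±20% relative,
not exactly. Only plain/pyramidal TIFF and PNG inputs are supported;
vendor whole-slide formats are out of scope.
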