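# Methods

## Problem and scope

Clinical PET segmentation feeds two quantitative endpoints: metabolic
tumor volume (MTV, the physical volume of the segmented lesion in mL)
and total lesion glycolysis (TLG, MTV times the mean SUV inside the
segmentation, in g). Segmentation algorithms, however, are almost
always ranked by task-agnostic similarity scores against a reference
mask — the Dice similarity coefficient (DSC), Jaccard coefficient
(JSC), and Hausdorff distance (HD). These two views need not agree: an
algorithm can overlap a reference boundary well while estimating MTV
poorly, and vice versa. This package builds the full apparatus to
exhibit and quantify that discordance on simulated cohorts where the
truth is exact rather than a human surrogate: a phantom generator, four
conventional segmentation algorithms, a configurable per-slice U-net,
MTV/TLG quantification, both FoM families, cohort statistics, and a
per-case concordance analysis.

## Phantom model

Each synthetic patient is a piecewise activity map on a 3-D voxel grid:
a uniform background (`background_suv`) plus a tumor of mean uptake
`tumor_suv_mean` whose support is a sphere, a volume-preserving random
ellipsoid, or a "lumpy" union of a core sphere with 3–5 seeded surface
lumps (the lumpy class exists so that HD is exercised by genuinely
non-spherical shapes). Intratumor heterogeneity is a smoothed Gaussian
random field restricted to the tumor, rescaled to a configurable SD and
floored so the tumor never drops below background. Imaging applies a
Gaussian PSF (FWHM per axis, mm), then adds white Gaussian noise in SUV
space, then clips at zero (SUV is nonnegative). Blur uses
edge-replicating boundary handling so a uniform background is preserved
and total activity is conserved for interior tumors.

Ground truth is the *pre-blur* support: true MTV is its voxel count
times the voxel volume, true TLG is true MTV times the mean noiseless,
unblurred activity inside the support. This is the deliberate advantage
of simulation over expert delineation — the truth is exact, so
normalized errors are attributable to the algorithms alone.

What the generator does **not** model: projection-domain (Poisson)
noise and reconstruction, CT anatomy, respiratory motion, multi-lesion
disease, and non-Gaussian texture. Passing results therefore speak to
the behavior of segmentation and quantification under partial-volume
blur and image-domain noise, not to reconstruction artifacts or
anatomical confounders.

Cohorts draw tumor diameter and uptake from truncated lognormals,
background from a uniform range, and assign per-case "scanner" presets
(PSF width, noise SD, voxel grid) round-robin. Defaults are era-typical
whole-body FDG-PET scales: 3–4 mm voxels, 64×64×48 grids, PSF FWHM
6.5–8.5 mm, diameters 12–45 mm (median ≈ 19–25 mm), tumor:background
contrast around 6–12:1, noise SD 0.3–0.45 SUV. The full cohort is a
pure function of its configuration and one integer seed (per-case child
seeds are spawned from it).

## Segmentation algorithms

All algorithms operate inside an analysis ROI standing in for clinician
localization: the truth bounding box dilated by 8 voxels (a margin, so
the true boundary itself is not leaked). Every returned mask is a
single 26-connected component inside the ROI and carries provenance
metadata.

**SUVmax thresholding.** Threshold = fraction × ROI maximum; voxels
with SUV ≥ threshold (≥ so that fraction 1.0 keeps the peak voxel),
reduced to the 26-component containing the max-SUV voxel, scan-order
tie-break. The threshold is relative, so the mask is invariant to
positive rescaling of the image.

**Snakes.** Morphological Chan–Vese active contour run per axial slice,
initialized as a disk around the in-slice maximum; the bright phase is
taken as the object and the in-slice component grown from the peak is
kept. Slices whose maximum falls below half of the ROI maximum are
skipped (they contain only background and blur halo). Slice results are
stacked and reduced to the largest 3-D component. A contrast-free image
yields an empty mask flagged `degenerate` in provenance — no boundary
exists for a region-based contour, and that is a result, not an error.

**MRF-GMM.** Two-component Gaussian mixture over ROI intensities with a
Potts smoothness prior of strength β on the 6-neighborhood. Fitting
alternates EM parameter updates (responsibilities modulated by the
current label field's neighbor votes) with checkerboard ICM label
updates; at β = 0 the procedure is exactly a plain EM Gaussian mixture.
Initialization is a deterministic scalar 2-means whose centers start at
the 1st/99th intensity percentiles: tumors typically occupy a small
fraction of the ROI, and a median split would seed both components
inside the background. M-step variances are regularized by 1e-6 × the
ROI intensity variance (the clip at SUV 0 creates an exact point mass
that a component can otherwise collapse onto); a variance-collapse
error is raised only for truly degenerate (near-constant) input, after
one jittered restart. The tumor is the higher-mean class.

## U-net

The network is a standard 2-D U-net segmenting volumes per axial slice,
written directly in NumPy with hand-coded backpropagation and an Adam
optimizer — at this scale (64×64 slices, 8–16 base filters) it trains
in seconds per epoch on one CPU and is bit-for-bit deterministic under
a seed, which the depth/loss experiments and the reproducibility
contract exploit. Backpropagation is validated against central finite
differences in the test suite.

Depth D counts the paired convolutional blocks (two 3×3 convolutions +
ReLU) in the encoder and, symmetrically, in the decoder; a bottleneck
block with dropout bridges them. Filters double per level. The total
convolution count is 5D + 3 (2 per paired block × 2D blocks, 2 in the
bottleneck, D up-sampling convolutions, 1 output 1×1). Inputs are
normalized by the per-volume SUV maximum (recorded in provenance), so
the network sees scale-free images across simulated scanners.

Losses: binary cross-entropy (mean over the slice, probabilities
clipped to [1e-7, 1 − 1e-7]), soft Dice (smoothing constant 1.0 applied
when truth and prediction are both empty, so an empty-empty slice
scores a loss of 0), and their λ-mix (λ = BCE weight; λ = 1 and λ = 0
reduce exactly to the pure losses). The default λ sweep is {0, 0.2,
0.4, 0.6, 0.8, 1.0} — six evenly spaced values including both
reductions. Gradients are taken with respect to pre-sigmoid logits.

Cross-validation folds split by case, never by slice. Inference
restacks per-slice probabilities to the volume grid, thresholds at 0.5
(exactly 0.5 counts as foreground), and keeps the largest 26-connected
component. Checkpoints are written as `.npz` weight archives with a
JSON sidecar (config, seed, fold metrics).

## Figures of merit and statistics

DSC = 2|A∩B|/(|A|+|B|), JSC = |A∩B|/|A∪B| (both defined as 1.0 with a
degeneracy flag when both masks are empty), and HD is the full
100th-percentile symmetric Hausdorff distance between voxel-center
point sets in physical mm (no percentile softening). The identity
JSC = DSC/(2 − DSC) and agreement with brute-force set/distance oracles
are enforced in tests to 1e-10.

Task-based FoMs: per-case normalized error NE = (estimate − truth)/truth
and its absolute value aNE; the ensemble normalized bias is the
unweighted mean NE over the cohort (×100, in %), with an absolute
variant |mean| because signed errors can cancel. Normalization is by
the true value and averaging is per-case with the cohort as the
empirical distribution of true values; a binned-by-truth weighting is a
possible alternative but per-case averaging is the default.

Cohort summaries report each FoM as mean and two-sided 95% t-interval
(n − 1 df) and compare algorithm pairs with two-sided paired t-tests at
the 0.05 level, one test per FoM with no multiplicity correction. An
all-zero-difference pair is reported as P = 1.0 with a degeneracy flag
rather than crashing on the undefined statistic.

Per-case concordance: for a pair (A, B), signed B−A deltas in each FoM;
orientation is higher-better for DSC/JSC and lower-better for HD and
aNE. A case is discordant when the task-agnostic delta and the
task-based delta point in opposite "better" directions; exact-zero or
undefined deltas form a separate tied stratum, so quadrant counts plus
ties always partition the cohort. The discordant-count statistic is
this package's operationalization of reading a delta-vs-delta scatter
diagram; no standard numeric definition exists.

## The discordance demonstration cohort

`configs/discordance_cohort.yaml` ships a seeded 50-case configuration
under which SUVmax40% matches or exceeds SUVmax50% on mean DSC while
carrying a strictly larger ensemble normalized MTV bias, with at least
one individually discordant case — the inversion that motivates
task-based evaluation. The mechanism is deliberate: noise inflates the
observed SUVmax by ≈10–20%, which places the *true* boundary between
the 40% and 50% isocontours of the blurred tumor. The 50% mask then
underestimates from inside the boundary, the 40% mask overestimates
from outside by a comparable contour offset; the cubic map from radius
to volume punishes the outward offset more (larger |MTV error|), while
Dice's concavity penalizes a superset less than a same-offset subset
(equal or better DSC). High contrast (≈ 9:1 median), moderate noise
(0.45 SUV), and diameters around 2–4× the PSF FWHM hold the cohort in
this regime. This is a demonstration configuration, not a claim about
every acquisition protocol.

## Problem sizes and numerical choices

Default experiment scales are chosen to run comfortably on a single
CPU: 50-case cohorts for the conventional-algorithm studies, ~30-case
cohorts with a held-out test split and a handful of epochs for the
U-net contrasts, 64×64×48 grids throughout. Determinism is end-to-end:
one global seed fans out to stage seeds via `numpy.random.SeedSequence`
spawning, and a rerun of `run` with the same config and seed reproduces
every CSV/JSON report byte for byte.

Known limitations: image-domain noise is a simplification of
reconstruction noise (no spatial correlation beyond the PSF, no
count-rate dependence); the Snakes and MRF-GMM implementations are
faithful to their algorithm families rather than to any specific
clinical software; TLG's unit of grams rests on the conventional
SUV ≈ g/mL density identification; and empty predictions are scored
DSC/JSC = 0 with an undefined (NaN) HD, flagged degenerate, which
slightly favors algorithms that always return something.
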