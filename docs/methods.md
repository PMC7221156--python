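# Methods

This note records the models, conventions and design choices behind
`repeatomics`, in the spirit of a package's statistical documentation: what
is computed, under which assumptions, and where the genuinely open choices
were made.

## Data model and coordinate conventions

A scan is a pair of coregistered 3D volumes — T2w (arbitrary units) and ADC
(10⁻⁶ mm²/s-scaled units) — on one axis-aligned grid, with a gland mask and
one or more lesion masks. The package does not register modalities or
timepoints: inputs are assumed pre-resampled to a single grid, and masks
must match their volume's grid to 10⁻³ mm in spacing and 10⁻² mm in origin
(stricter equality is brittle across NIfTI writers). Internally everything
is voxel-indexed, 0-based; world coordinates (origin + index·spacing) are
used only where physical distance matters — the habitat sphere, centroids,
and all mm-denominated shape features. Rotated affines are not supported.

## Gland z-score standardization

MR intensities carry no biological reference scale, so each modality of each
timepoint is standardized by the gland: subtract the gland mean, divide by
the gland **population** standard deviation (÷N; at gland voxel counts the
n−1 distinction is immaterial, but one convention must be fixed for
reproducibility). The transform is applied to the whole volume so lesions
and habitats inherit gland-relative intensities. Each timepoint uses its own
gland statistics. A constant gland is rejected rather than silently passed
through. Z-scoring is affine, so it cannot change which voxels a
threshold-based habitat selects, and it leaves all fixed-bin-number
quantized texture features identical — only absolute-scale features (first
order statistics, Laws, wavelets, some shape/intensity hybrids) respond
to it.

## Habitat regions

A habitat is a contiguous restricted-diffusion sub-region converged
automatically from a marked lesion; low ADC is the malignancy surrogate.

* **Sphere habitat** — a sphere of fixed diameter (default 15 mm) centered
  at the lesion's unweighted centroid in world mm, clipped to the gland.
  Within sphere∩gland, voxels with ADC ≤ μ − k·σ are kept (μ, σ from
  sphere∩gland ADC). The deviation multiplier k is exposed (default 1.0): the
  underlying "distributional deviation" rule is not published precisely, so
  k is a parameter rather than a constant. If the strict threshold selects
  nothing (e.g. σ = 0 in a uniform neighborhood), the rule falls back to
  ADC ≤ μ. The largest connected component is returned; it may extend
  beyond the lesion but never beyond the gland.
* **Within-lesion (median) habitat** — the largest connected component of
  lesion voxels at or below the median lesion ADC (midpoint-interpolated,
  ties included, so the result is never empty and always inside the lesion).

Connectivity is 26 by default ("most contiguous" favors the permissive
neighborhood); size ties between components are broken by the smallest
linear voxel index, making convergence deterministic. Habitats are converged
once per timepoint from that timepoint's **raw** ADC and mapped to both
modalities.

## The 307-feature catalog

Features are identified `F<k>:<name>`, k = 1..307, in three categories:
C1 size/shape (45), C2 intensity/histogram/texture-matrix (107), C3
filter-bank textures (155). Within each family the order follows the IBSI
reference feature order: first-order statistics F1–F19, intensity-histogram
F20–F42, shape F43–F90 (with three local-intensity features at F55–F57),
co-occurrence F91–F115 (25), run length F116–F131 (16), size zone F132–F147
(16), NGTDM F148–F152 (5), Laws F153–F277 (125 = 5³ ordered kernel
triples over L5/E5/S5/R5/W5), wavelet F278–F307 (15 subbands × {mean
absolute coefficient, energy}). Exact membership of unnamed slots (e.g. the
volume-at-intensity-fraction curve at eight fractions plus their 10–90
difference) is this package's published convention.

### Quantization

Texture-matrix families operate on a fixed-bin-**number** quantization
(default Ng = 32) over the in-ROI min–max range, with right-closed bins
(the minimum maps to level 1, the maximum to Ng); a constant ROI maps to
level 1. Fixed bin number makes raw and z-scored texture features
comparable, consistent with standardization having modest effects on
texture. Ng = 32 balances matrix occupancy against ROI sizes of a few
hundred to a few thousand voxels.

### Texture conventions

* GLCM and GLRLM: 13 unique 3D directions at Chebyshev distance 1; features
  computed per direction, then averaged (the `avgCooc_3D`/`avg_3D` naming).
  Matrices are symmetric; directions with no voxel pairs are skipped.
* GLSZM: single matrix, 26-connected zones. NGTDM: 26-neighborhood
  restricted to in-ROI voxels, IBSI ε-guard (10⁻¹²) so a constant ROI gives
  coarseness 10¹² and zero for the contrast-type features.
* Texture is computed on the voxel grid ignoring spacing anisotropy; shape
  features are spacing-aware (mm, mm², mm³), matching how the units are
  printed in the feature names.
* Degenerate values are emitted as NaN, logged, and excluded pairwise
  downstream; on non-pathological ROIs every feature is defined.

### Filter-bank features

Laws features convolve with separable kernel triples
(L5 = [1,4,6,4,1], E5 = [−1,−2,0,2,1], S5 = [−1,0,2,0,−1],
R5 = [1,−4,6,−4,1], W5 = [−1,2,0,−2,1]) and reduce to the mean absolute
response over ROI voxels — the classic texture-energy statistic. Volumes
are extended by mirror reflection; computation runs on the ROI bounding box
plus a 2-voxel margin, sharing 1D passes across triples. Wavelet features
use a two-level undecimated (stationary) Haar transform of the bounding box
(padded to a multiple of 4, symmetric). Subbands are indexed C1–C7
(level-1 details LLH…HHH over axes 0,1,2), C8–C14 (level-2 details, same
order), C15 (level-2 approximation); the exact original basis behind this
15-subband indexing is not recoverable, so Haar/undecimated is this
package's documented choice. Weighted centroids shift intensities to be
non-negative (w = v − min) so z-scored inputs cannot produce unbounded
weighted centers of mass; for uniform ROIs the weighted and geometric
centroids coincide exactly.

## Repeatability statistics

CCC uses population moments; both-constant-and-equal vectors give 1,
constant-but-unequal give 0 (the formula's limit), and at least 3 complete
pairs are required. DR divides the mean absolute test−retest difference by
the **pooled** test∪retest range — the most inclusive reading of "observed
interpatient variability" — clipped to [0, 1], with a zero pooled range
giving 0. Pairs containing NaN are dropped; features with fewer than 3
complete pairs are recorded as NaN and excluded from counts, with a logged
warning. A feature passes cutoff c only jointly: CCC ≥ c **and** DR ≥ c.

Note one structural consequence: features that are constant across the whole
cohort at both timepoints (e.g. the quantized histogram maximum, which is
always Ng for any non-constant ROI) have a degenerate pooled range and hence
DR = 0 even when test ≡ retest. In the noiseless limit every feature
attains CCC = 1, and every feature with a non-degenerate range attains
DR = 1; the structurally constant handful is screened out by the DR filter,
which is the intended behavior — a feature with no biological range carries
no discriminative information.

## Redundancy reduction

R² between two features is the squared Pearson correlation of their
subject-wise values after averaging test and retest per subject. Reduction
is greedy and deterministic: among surviving features take the one with the
highest DR (ties broken by catalog index), eliminate every other feature
with R² ≥ the cutoff against it, recurse on the remainder. Every eliminated
feature is guaranteed R² ≥ cutoff with at least one representative; the
survivors are *not* certified pairwise independent (chains broken by greedy
order may leave correlated survivors). Constant features have R² = 0 against
everything and survive on their own merits. Whether the original procedure
was greedy or component-based is unstated; greedy honors both published
rules (group by R², representative = highest DR) and is reproducible.

The summary table applies reduction **once**, to the set passing the base
(lowest) cutoff; each row then counts survivors whose CCC and DR also reach
that row's cutoff. This matches the selected-feature lists being published
at the base cutoff and guarantees the nested, monotone structure of the
count table. Default R² cutoffs are 0.99 and 0.95.

## Synthetic data

### Phantom cohort

Each patient is an ellipsoidal gland (default semi-axes 18×14×12 mm in a
48×48×16 grid at 1×1×3 mm — an axial-MR-like anisotropy) containing a
spherical lesion (radius 6 mm ± 15% between patients) with a two-compartment
ADC profile: a strongly restricted core (default 750 vs 1400 in the gland,
core radius 0.8 of the lesion radius ≈ half the lesion volume) and an
intermediate rim. T2w is darker in the lesion. Per-patient tissue means vary
with CV 8% (between-patient spread — the DR's denominator). Frozen Gaussian
texture (ADC SD 150, T2 SD 60) plays tissue heterogeneity; each timepoint
then adds fresh Gaussian noise at `retest_noise_sd` (default 0.3) times the
texture SD, and the lesion mask is independently jittered per timepoint by
random dilation/erosion with a structuring element of world radius ≤
`boundary_jitter_mm` (default 1 mm), emulating independent delineation.
With zero noise and zero jitter, test and retest are bitwise identical.

What the phantom does **not** emulate: Rician noise floors (Gaussian keeps
the designed algebra exact and a Rician difference is immaterial at these
SNRs), endorectal-coil artifacts, zonal anatomy, field-strength or scanner
effects, and realistic inter-reader segmentation behavior. Passing tests on
phantoms therefore demonstrates the pipeline's correctness and its designed
statistical behavior, not clinical-grade repeatability estimates; phantom
survivor counts are far higher than a real 15-lesion cohort's.

Habitat-core recovery is quantified as the Dice overlap between the
within-lesion habitat and the planted core, using the planted lesion mask
at default voxel noise (cohort mean ≈ 0.82–0.87 across seeds). Delineation
jitter is deliberately excluded from this measurement: it is a test–retest
perturbation whose effect the repeatability statistics themselves quantify,
and folding it into the recovery score would conflate segmentation error
with convergence error.

### Designed feature matrices

For feature j and subject i: Test = μ_ij + e₁, Retest = μ_ij + e₂ with
μ ~ N(0, σ_b²), e ~ N(0, σ_w²), and σ_w chosen so the population
CCC = σ_b²/(σ_b² + σ_w²) hits the target (target 0 uses μ ≡ 0; target 1
uses σ_w = 0, giving sample CCC exactly 1). Duplicate blocks replicate a
feature through exact affine maps — population R² = 1, DR unchanged (DR is
affine-invariant) — to exercise redundancy collapse. Recovery of a CCC
target is assessed through the mean sample CCC over replicate features: a
single sample CCC at n = 200 has sampling SD ≈ 0.064 near target 0.3, so
only the replicate mean concentrates tightly enough to be a meaningful
check.

## Problem sizes used in the test and acceptance runs

Unit and acceptance tests run on 4×4×4 oracle ROIs (Ng = 4), 3–10-patient
phantoms on the 48×48×16 grid, designed matrices at n = 200 with 30
features, and 40–100 replicates for recovery rates — sizes chosen so the
whole suite completes in well under a minute apart from the end-to-end
phantom runs, while keeping every statistical assertion comfortably inside
its sampling tolerance.

## Known limitations

* No DICOM/DICOM-SEG ingestion; NIfTI only (conversion is upstream).
* Axis-aligned grids only; rotated affines are rejected implicitly by the
  spacing/origin model.
* Numeric equality with any particular in-house extractor is out of scope;
  the implementation is validated against exhaustive brute-force oracles
  and published invariants instead.
* Texture features ignore spacing anisotropy by convention; on strongly
  anisotropic grids, direction-averaged matrices mix physical scales.
* The greedy reduction is order-dependent by design; a different but equally
  defensible iteration order would select different representatives.
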