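# Methods

This note documents the models, algorithms, defaults, and numerical choices
behind `shgfiber`, and what the synthetic-data tests do and do not
demonstrate about real SHG data.

## Imaging model and units

An SHG field of view (FOV) is a non-negative grayscale grid, 2D `(y, x)` or
a z-stack `(z, y, x)`, with an in-plane pixel size in µm (default 0.497 µm,
a typical 25× two-photon acquisition; tiled scans default to 0.53 µm with
3 µm z-steps). The SHG signal is frequency doubled, so detection sits at
half the excitation wavelength (860 nm → 430 nm); the package exposes this
as a configuration check, not an optics simulation.

Z-stacks are maximum-intensity projected to 2D before segmentation by
default. Per-slice segmentation is available, but all shipped analyses are
2D: the percent-volume readout is defined per FOV grid and is identical in
spirit either way, while projection is the more robust default for thin
(5 µm) sections where a stack adds little independent signal.

## Preprocessing

A median filter with a disk footprint (default radius 1 px) suppresses
shot-noise outliers, then a global intensity percentile (default 25th) is
subtracted and the result clipped at zero. Radius 0 / percentile 0 are exact
identity settings, which the tests rely on.

## Fuzzy c-means segmentation

Intensities are clustered with fuzzy c-means implemented from scratch
(alternating updates of memberships and centroids). Choices:

- **c = 2 clusters** (background vs fiber) by default; c = 3 is exposed for
  heterogeneous backgrounds (diffuse non-fibrillar signal forms a middle
  class; the top cluster is always the fiber class).
- **m = 2.0 fuzziness**, the conventional value. As m → 1⁺ the partition
  hardens; the test suite checks agreement with k-means at m = 1.05.
- **Deterministic quantile initialisation** (centroids at the (k + ½)/c
  intensity quantiles) so segmentation needs no seed; seeded random
  initialisation is available. If skewed data collapse the quantiles, the
  centroids fall back to evenly spaced unique values.
- **Convergence** when the maximum centroid movement falls below
  `tol × intensity range` (default 10⁻⁵), cap 300 sweeps. The objective is
  recorded each sweep and is non-increasing by construction; a final
  membership half-step makes the returned `(U, V)` pair mutually
  consistent. Centroids are returned sorted ascending.
- **Zero-distance rule**: a voxel exactly on a centroid gets membership 1
  there, 0 elsewhere.
- **Defuzzification by strict argmax**: a voxel is fiber iff its membership
  in the top-centroid cluster strictly exceeds every other; ties go to
  background. This is well defined for any c, unlike a 0.5 cutoff.
- Clustering uses intensity only. Spatial coherence is enforced downstream
  by the shape filter, not inside the clustering.
- A constant image cannot be clustered and yields an empty mask with a
  warning; segmentation is invariant to affine intensity rescaling
  `x → a·x + b` (a > 0) because memberships depend only on distance ratios
  and the tolerance is range-relative.

Correctness is checked against a brute-force restart oracle: on 200-point
1D inputs the deterministic run reaches the best objective found by 50
randomly initialised plain-loop alternating-optimisation runs (within
10⁻⁶; measured gap ~10⁻¹³).

## Shape filter and morphometry

Connected components (8-neighbour in 2D, 26 in 3D) are measured as:

- **Length**: the longest geodesic over the skeleton's pixel adjacency
  graph (diagonal steps weighted √2; double-sweep Dijkstra, exact on
  trees), plus the distance-transform value at the two path endpoints to
  compensate skeletonization end erosion. A 50 × 3 px bar measures within
  1 px of its true 49-px span.
- **Width**: 2 × mean Euclidean distance transform sampled on the skeleton.
  Both measures subtract half a pixel per side because the EDT counts
  pixel-centre distances.
- Components erased entirely by thinning (1–2 px specks) are treated as
  points (length 0), so they never pass the filter.

A component is kept iff length ≥ 10 µm, width ≤ 10 µm, and length/width
aspect ≥ 2. These thresholds are free parameters of the method (no
published numeric values exist for the original in-house criteria); the
defaults remove compact blobs (a disk has aspect ≈ 1) and small specks
while keeping anything fiber-shaped, and they travel with every output.

**Percent fiber volume** is 100 × fiber voxels / all voxels of the FOV grid
— the denominator is the whole FOV, not a tissue mask (a tissue-mask
denominator can be applied by the caller). Patient aggregation is the
arithmetic mean ± SE over that patient's FOVs; a single-FOV patient gets
SE 0 and is identifiable via `n_fov = 1`.

## Stitching

Tiles carry nominal stage origins. The first tile anchors the mosaic; each
subsequent tile is registered against the placed tile it nominally overlaps
most, by exhaustive search of integer shifts within ±20 px (default) of the
nominal, maximising normalized cross-correlation of the overlap. Ties
prefer the shift closest to nominal. Integer-pixel registration only: the
downstream statistic is a volume fraction, insensitive to subpixel shifts.
Overlap voxels blend by maximum — idempotent when crops agree and free of
seam dimming for sparse-bright signal. Guard rails: the nominal overlap must be
at least 32 px in each dimension; a flat overlap, or a best correlation
below 0.30 (e.g. pure noise), falls back to the nominal shift with a
warning. On synthetic quadrant splits with ≤ 3 px nominal jitter the round
trip is bit-exact, so stitched-then-quantified equals quantified-uncut.

## Statistics

- **t-test**: pooled-variance unpaired Student test (Welch optional),
  accepting raw values or `(mean, sd, n)` summaries so published summary
  rows can be reproduced; one-sided p is half the two-sided p when the
  observed direction matches the alternative. The fixed alternative for the
  fiber analysis is recurrent > non-recurrent.
- **Random-intercept model**: `log(volume) ~ recurrence + (1 | patient)`,
  REML via statsmodels MixedLM. The natural log is used (recorded in the
  fit object); non-positive volumes error by default, with an opt-in
  offset policy `log(x + δ)`, δ = half the smallest positive volume —
  silent imputation is deliberately not the default. The fixed-effect
  p-value uses the Wald normal approximation (recorded as `df_method`);
  simulation shows the one-sided type-I rate at α = 0.05 stays inside the
  99% binomial band over 1000 cohorts of the 12-vs-14 design.
- **Median split**: threshold at the sample median of patient mean volumes;
  strictly greater → high, ties → low (policy recorded in the output).
- **Survival**: Kaplan–Meier product-limit curves; log-rank test from the
  hypergeometric O/E/V table accumulated over pooled event times; hazard
  ratio primarily as `(O_high/E_high)/(O_low/E_low)`, with the Cox
  partial-likelihood estimate reported alongside as a labelled alternative.

Simulations document two properties worth knowing. First, the FOV-level
mixed model has one-sided p below the patient-level t-test p in the
majority of replicates when within-patient scatter is large — the reason
the chain runs both levels. Second, the O/E hazard-ratio estimator
attenuates strong contrasts: at a true hazard ratio of 2.7 on 26 patients
the median estimate is ≈ 2.4 when patients are split on the latent true
mean volume (the grouping the hazard actually used — clean parameter
recovery), and ≈ 2.0 when split on the observed mean, because
dichotomising on a noisy covariate misclassifies patients near the median.

## Gene-panel filter

Significance calls use `|log2FC| > 0.5` (strict; ~1.4-fold) and
`padj ≤ 0.05` (non-strict). The fold-change rule is symmetric in magnitude:
the down-regulated side means `log2FC < −0.5`, the only reading under which
published down-regulated panel genes are callable at all. Benjamini–
Hochberg adjustment (statsmodels step-up, capped at 1) backs the synthetic
tables; the shipped 39-gene reference table keeps its published padj
values, on which exactly one gene (CD38, padj 0.0531) fails the filter.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the optics:

- **Images**: fibers are directionally persistent random walks (persistence
  0.9, length ~ N(80, 20²) px, width ~ N(3, 0.75²) px) dilated to width and
  drawn additively at intensity 200 over a background of 10, with Gaussian
  read noise (σ = 3) and scaled-Poisson shot noise — the standard
  photon-counting approximation. When a target volume fraction is set,
  fibers are added until the truth mask reaches it (`n_fibers` caps the
  count); the truth fraction lands within a few percent of target at 512².
  Circular blobs emulate non-fibrillar bright structures and are excluded
  from the truth mask by construction.
- **Cohorts**: per-patient FOV counts uniform on [6, 18]; log percent
  volume = 0.7 + 0.5·1{recurrent} + b + ε with b ~ N(0, 0.5²) between
  patients and ε ~ N(0, 0.6²) within — baseline volumes ≈ 2%, recurrent
  ≈ 1.65× higher, right-skewed on the raw scale as real fractions are.
- **Survival**: exponential event times at base hazard 0.1 per unit time
  (an added parameter; some baseline is required), multiplied by the true
  hazard ratio (default 2.7) for patients whose *true* mean volume exceeds
  the cohort median, with independent Exp(0.05) censoring. Linking hazard
  to the true mean rather than the estimate makes hazard-ratio recovery a
  parameter-recovery exercise uncontaminated by measurement error.
- **DE tables**: null genes with N(0, 0.2) log2FCs and Uniform(0,1)
  p-values; planted genes carry their stated effect plus N(0, 0.02) noise
  and p ~ 10^−U(8,15).

Everything is bit-reproducible given the seed.

**What passing tests show — and don't.** The generator produces bright
curvilinear structures on dark noise with controlled truth, which validates
the segmentation/filter/quantification machinery and the statistical chain
end to end. It does not reproduce H&E-derived background heterogeneity,
out-of-focus light, fiber crossings with sub-resolution gaps, staining
artefacts, or spatially correlated noise; accuracy numbers from these tests
(e.g. volume recovery within ±5% relative at 512², Jaccard ≈ 0.94) are
upper bounds on what identical settings achieve on real tissue, where
preprocessing and threshold choices matter more.

## Problem sizes used in shipped computations

The test suite and acceptance script use: 20 seeds per truth level at 512²
for volume recovery (levels 1/5/10/20%); one 1200² section for the
stitching round trip; 1000 simulated cohorts for type-I calibration;
500 (tests) / 300 (script) cohorts for hazard-ratio recovery; 200-point
inputs and 50 restarts for the FCM oracle. These sizes give stable
estimates of each quantity while keeping a full run in the low minutes.

## Known limitations

- Intensity-only clustering cannot separate non-fibrillar structures that
  are both bright and elongated; the shape filter is the only guard.
- The skeleton geodesic underestimates the length of strongly self-crossing
  fibers (the skeleton graph shortcut through the crossing).
- Stitching assumes translation-only misalignment; rotation or scale drift
  between tiles is out of scope.
- The O/E hazard ratio is attenuated for strong effects (see above); use
  the Cox estimate when an unbiased ratio matters.
- MixedLM's normal-approximation p is mildly liberal for very few patients;
  the calibration simulations bound the effect for designs near 12 vs 14.
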