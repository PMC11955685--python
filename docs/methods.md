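# Methods

This note documents the models, the synthetic data-generating process, the
numerical choices, and the known limits of `conngrad`.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Gradient estimation

**Affinity.** For regions i and j, the similarity of connectivity profiles
is computed on rows i and j of the connectome with the entries at positions
i and j removed, so the structural zero of the diagonal never dilutes the
similarity.  Kernels: `cosine` (default), `spearman` (rank correlation,
negative values clipped to 0 — diffusion operators need non-negative
weights), and `normalized_angle` (1 − arccos(cos)/π).  The main analysis
runs on the raw, unthresholded connectome; `sparsify` (zeroing the weakest
fraction of unordered pairs, ties broken toward keeping lower-index pairs)
exists for sensitivity variants at sparsities such as 0.7–0.9.

**Diffusion map.** With degree diagonal D of the affinity W, the operator is
`W' = D^(−α) W D^(−α)`, `P = D'^(−1) W'`.  Eigenvectors are obtained exactly
from the dense symmetric conjugate `D'^(1/2) P D'^(−1/2)` (`scipy.linalg.eigh`),
converted to right eigenvectors of P, and normalized so the trivial constant
eigenvector (discarded) equals 1.  Defaults α = 0.5, t = 0; the t = 0
scaling is the multi-scale weight λ/(1−λ), and t ≥ 1 uses λᵗ.  Ten
components are computed; the first three are analyzed.  Explained variance
is λᵢ^q / Σⱼ λⱼ^q over the retained nontrivial spectrum with q = 2 by
default (`variance_power=1` switches to first-power weighting); the
percentage printed for a template therefore depends on both the retained
count and q, and is reported, not asserted.

**Template and alignment.** The template embeds the element-wise mean
connectome of the whole cohort.  Eigenvector sign is arbitrary, so the
template fixes orientation deterministically: gradient i is flipped so its
covariance with the centroid x, y, z coordinate (cycling beyond the third)
is non-negative.  Individuals are aligned by orthogonal Procrustes
(`S = UVᵀ` from the SVD of `GᵀM`; rotation/reflection, no scaling, no
translation) and inherit the template's orientation.  Degenerate (tied)
eigenvalues are ordered by the sign of the first nonzero eigenvector
element and logged; the subspace is then only defined up to rotation and
Procrustes absorbs the ambiguity.

## Group statistics

Responses are always the subjects' *aligned* gradient scores.  The design
is [intercept, group, age, sex] with patient = 1 and male = 1 (coefficient
signs depend on this coding).  Hotelling's T² for the group contrast uses
the error covariance Σ̂ = EᵀE/(n − rank X) and the exact F reference
`F = T² (n − p − k + 1)/(k(n − p))` with (k, n − p − k + 1) degrees of
freedom; with no covariates this reduces to the classical two-sample
formula, which the tests assert to 1e-8.

FDR families: 7 networks per network-level analysis; all cortical regions
per region-level analysis; univariate per-gradient families corrected
separately per gradient (a joint 7 × 3 correction is a caller choice — pass
the concatenated p-vector).  Post-hoc per-gradient contributions use
p < 0.05/3.  Family sizes are recorded in a sidecar JSON next to each
stat-map table.

## Spin permutation null

The variant implemented is centroid-rotation with nearest-neighbor
reassignment, which works on parcel tables and needs no vertex spheres:
draw a Haar-uniform rotation (QR with sign correction, determinant +1),
rotate the left-hemisphere centroids, apply the x-mirrored rotation to the
right hemisphere, and give each region the value of the region whose
original centroid is nearest (maximal dot product; ties to the lowest
index) within the same hemisphere.  The reassignment is not a bijection;
the duplication rate is logged and stays near 10% on the default synthetic
geometry.  Permutation p-values carry the +1 correction and are two-tailed
on |r|.  Only the first map is spun — with exchangeable nulls the asymmetry
is immaterial, and it keeps the second map's values exact.

## PLS transcriptomics

Single-response PLS with sequential covariance-maximizing extraction and
predictor deflation (NIPALS-equivalent); the first weight vector is
proportional to Xᵀy, which the tests use as a closed-form oracle, and
scikit-learn's implementation serves as an independent cross-check.
Variance explained per component is the incremental R² of the response on
the accumulated scores.  Permutation significance refits the model on
spin-permuted (default) or shuffled responses and compares cumulative
variance explained, reporting both joint and per-component p-values.

**Bootstrap Z.** Regions are resampled with replacement, the model refit,
and each bootstrap weight vector re-signed to agree with the original
before the SD is taken — without re-signing, component sign flips inflate
the SD and destroy the Z calibration (regression-tested).  Z is computed on
the *covariance scale* (unit weight × extraction norm): bootstrapping the
unit-normalized vectors shrinks every SD by the systematic noise inflation
of the resampled vector norm (accumulated over all genes, sizeable when
genes outnumber regions) and leaves the null Z overdispersed by ~20% even
for white-noise genes.  Significant genes come from two-sided normal tests
on Z with Benjamini–Hochberg FDR, split by sign into PLS+/PLS− sets; the
realized |Z| at the FDR boundary is reported rather than fixed a priori.

The component analyzed is the one explaining the most response variance
(automatic argmax, manual override available).  The response is the
left-hemisphere region-level multivariate group statistic map,
standardized; a univariate-difference response is available via the library
API.

## Synthetic cohorts

The generator supplies the study conditions for all recovery and
calibration tests:

* **Geometry.** Each hemisphere occupies its own full unit sphere — the
  geometry spherical registration gives real hemispheres and the one spin
  rotations assume.  Left centroids are a Fibonacci lattice (quasi-uniform,
  like the near-equal-area parcels of real parcellations) under a random
  rotation; the right hemisphere is the exact x-mirror.  Networks are
  nearest-anchor caps, so labels are spatially contiguous.  Volumes are
  log-normal with unit median.
* **Connectomes.** Expected weight `exp(−d/ℓ)` in great-circle distance
  (ℓ = 0.75 rad) times a within-network boost (2.0), with unit-mean
  log-normal edge noise (σ = 0.3) drawn symmetrically per subject.  The
  patient effect multiplies *within-network* edges of the effect networks by
  1 + effect_size (default 0.3 on the somatomotor network): reweighting a
  region's within-community edges changes its connectivity profile shape
  and shifts the network along the gradients, whereas scaling all incident
  edges would rescale whole rows, to which the cosine kernel is blind.
* **Subcortical profiles.** Exponential decay in Euclidean distance from
  interior anchor points (radius 0.2–0.5), same noise model, optional
  multiplicative effect on designated structures.
* **Expression.** Gaussian random fields on the centroids with a
  squared-exponential kernel in great-circle distance, computed in
  mirror-symmetric coordinates (right hemisphere mapped onto the left
  sphere) so homotopic locations are maximally correlated and the field
  distribution is exactly invariant under the mirrored spin rotations.
  Length scale 0.2 rad: at the default parcel density (median neighbor
  distance 0.34 rad) this gives neighbor correlation ≈ 0.24 — moderate
  spatial autocorrelation; 0.3 rad would make independent maps
  near-duplicates at parcel resolution (neighbor correlation ≈ 0.5).
  Signal genes are the standardized target map plus one unit of field noise
  (gene–target correlation ≈ 0.7, i.e. strongly associated genes); all
  columns are standardized.
* **Covariates.** Age ~ Normal(62, 8) truncated to [45, 80]; sex
  Bernoulli(0.5); no group–covariate confound by default.

Default sizes — 100 regions, 2 × 25 subjects, 500 genes — keep a full
pipeline run around a second and the entire acceptance suite within a few
minutes; calibration tests use 60-region cohorts of 2 × 15 and recovery
tests the defaults.

**What passing tests do and do not show.**  The generator reproduces the
*structure* real pipelines operate on (modularity, distance decay,
bilateral symmetry, spatial autocorrelation, planted effects) but none of
the biases of the measurement process: no tractography distance/gyral
biases, no streamline-count statistics, no realistic folding geometry, no
probe-level expression noise or donor effects.  Recovery results therefore
validate the statistical machinery, not robustness to imaging artifacts.

## Numerical and degenerate-input policy

Matrices travel as TSV written at %.17g (lossless for float64; readers use
round-trip float parsing).  Readers reject NaN/Inf with cell coordinates.
Connectome symmetry is enforced at 1e-10, affinity diagonal exactly 1,
orthogonality of alignment transforms at 1e-8.  Disconnected affinity
graphs raise with the component memberships; all-zero connectivity rows
raise with the region index; constant responses raise rather than emit
undefined statistics; degenerate bootstrap resamples are redrawn and
counted.  One pipeline seed expands deterministically (SeedSequence) into
per-stage seeds, all recorded in the run manifest.

## Known limitations

* The region-resampling bootstrap underlying the gene Z assumes regions are
  exchangeable; under strong spatial autocorrelation it underestimates the
  sampling variability of map correlations, so the null Z is mildly
  overdispersed (~10% at the default smoothness) and the realized
  false-discovery proportion of the gene sets sits slightly above the FDR
  target.  A spatially aware resampling scheme would be the fix and is out
  of scope.
* With many genes and few regions (e.g. the 50 left regions of the default
  cohort) PLS fits most of any smooth response, so the permutation test on
  variance explained has little power and the bootstrap gene test is
  underpowered; the module's reference size for gene recovery is 100
  regions.
* The spin test's nearest-centroid reassignment duplicates ~10% of values
  per permutation on the default geometry; maps on very coarse parcellations
  would inflate this.
* Joint-embedding alignment (an alternative to Procrustes) is not
  implemented.
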