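# Methods

## Gradient construction

Per subject, node time series are correlated (Pearson; constant rows are an
error, the diagonal is excluded) and each row of the connectivity matrix
keeps its `ceil(density·(n−1))` largest off-diagonal values (default density
0.10, rank-based, values retained not binarized; ties at the cutoff are all
kept, so realized density can slightly exceed nominal). Cosine similarity
between sparsified rows is mapped to the normalized angle 1 − arccos(c)/π.
Cosines within 1e−14 of ±1 are snapped to ±1 before the arccos, because the
inverse cosine amplifies an O(eps) rounding error to O(sqrt(eps)) in the
angle.

The diffusion map uses anisotropic normalization with α = 0.5 and the
automatic diffusion-time scaling λ/(1−λ); both are configurable. The
spectrum is obtained through the symmetric conjugate of the transition
operator (eigendecomposition of D_W^{−1/2} W D_W^{−1/2}), which is
numerically stabler than a nonsymmetric solve; a genuinely independent
nonsymmetric full-spectrum eigensolve serves as the test oracle. A
disconnected affinity graph is an error (raising the density is the remedy);
silent regularization would change the spectrum. Explained ratios are each
retained eigenvalue's share of the nontrivial positive spectrum, so they are
sorted, non-negative, and sum to at most 1.

Ten components are retained by default; analyses downstream consume gradient
1 only. After alignment, gradient 1 is oriented so its mean over DMN-labeled
nodes is positive (primary-to-transmodal convention), configurable.

## Cross-subject alignment

`procrustes_align` iterates orthogonal (rotation/reflection, no scaling)
fits of each subject to a template, recomputing the template as the
component-wise mean, until the total disparity change falls below 1e−8 or
`n_iter` passes. Each step is non-increasing in total disparity. Because
single-subject embeddings of noisy data have near-degenerate spectra (their
leading eigenvalues are close, so components rotate freely under sampling
noise), the pipeline anchors alignment to a reference template computed from
the *group-mean* connectivity matrix rather than the mean of unaligned
subject embeddings. Both modes are supported and tested.

## Group statistics

Per-node OLS on [intercept, group, age (centered), sex]; the group
coefficient's t and two-sided p are computed in closed form, vectorized
across nodes. Cohen's d = t·sqrt(1/n1 + 1/n2) (covariate-adjusted, a
standard choice when effect sizes accompany GLM contrasts). The z map is
the signed normal quantile of the two-sided t p-value. Exact fits (all-zero
residuals up to rounding) are guarded to t = 0 rather than 0/0.

Cluster-extent inference permutes group labels and compares observed
supra-threshold (p < voxel_p) connected-component sizes to the null
distribution of maximum extents — exact under exchangeability, replacing
random-field corrections that need volumetric smoothness estimates this
matrix-level package does not see. Max-extent permutation p-values are
valid but discrete and therefore conservative; the calibration suite runs
the null check at voxel_p = 0.01 on 60-node maps because at 0.001 the null
max-extent distribution is almost entirely zero and the rejection rate is
unmeasurable. Missing clinical scores are handled by listwise deletion per
analysis.

## Topology

Graphs are binarized at each sparsity in 0.05–0.50 (step 0.05 by default; a
field-standard window, exposed in config). gamma = C/⟨C_rand⟩ and
lambda = L/⟨L_rand⟩ use 20 Maslov–Sneppen degree-preserving rewired
references per sparsity (10·|E| swap attempts each, on a flat edge list with
hash-set membership checks); sigma = gamma/lambda holds as an identity.
Clustering is computed from triangle counts and path length by sparse BFS
(compiled shortest-path routines, not per-node Python traversal), which is
what keeps per-subject curves affordable at calibration scale. On
disconnected graphs L is computed on the largest connected component —
deterministic and finite, at the cost of understating path length at very
low sparsities. AUCs are trapezoidal over the sparsity range.

## Spin test

Null maps are built by rotating parcel centroids with uniform random
rotations (QR of a Gaussian matrix, determinant fixed to +1) and
reassigning each parcel to its nearest original centroid. Hemispheres are
rotated with mirrored rotations and matched within hemisphere; this assumes
each hemisphere is represented as its own full sphere (the convention of
surface-registration spheres). Nearest-neighbor reassignment is not a strict
permutation — on the synthetic 150-parcel sphere about 10% of parcels are
duplicated per spin — which is accepted, as in the standard
rotate-parcellation approach. p-values are add-one smoothed (never zero) and
two-sided on |r| by default (one-sided available); empirical type-I error
under independent smooth Gaussian-process maps is within the binomial 95% CI
of 0.05.

## Transcriptomics

PLS (scikit-learn NIPALS) regresses the standardized z map on per-gene
z-scored expression. Component scores are sign-flipped so corr(scores, y) ≥
0. Component significance refits on spin-permuted maps and compares
explained y-variance. Bootstrap (regions resampled with replacement) gene
weights are sign-aligned to the original weight vector by dot product before
the SE is taken — components are sign-indeterminate and unaligned bootstraps
inflate SEs. Z = weight/SE, two-sided normal p, BH-FDR at q = 0.05, and
genes partition into PLS1+ (Z > 0), PLS1− (Z < 0) and none. The FDR
boundary on |Z| is re-derived from the data rather than fixed.

## Enrichment

Disorder-set overlap: the statistic is the mean PLS-Z over genes shared
between the PLS list and the target set; the null redraws gene sets of the
overlap's size from the background (plain, not expression-matched — a
config extension point). Marker-set overlap uses the overlap count with
equal-size resampled gene lists and BH-FDR across the marker sets. GSEA is
preranked with gene-label permutation: hits increment by |score|^p (p = 1
default), misses decrement uniformly, ES is the running-sum extremum of
largest magnitude, and NES divides by the mean |null ES| of matching sign —
so sets loaded at the negative tail of the ranking report negative NES.
Gene ids are harmonized by case-insensitive exact match only (no alias
resolution).

## Prediction

Linear-kernel epsilon-SVR (C = 1, epsilon = 0.1; assumptions, since no
canonical values exist) under leave-one-out cross-validation. Features are
standardized inside each training fold only; the held-out subject never
contributes to standardization or fitting, and a fold-isolation test checks
this exactly. Validity is a label-permutation test on LOOCV r (greater) and
MSE (less). Attribution weights come from an all-subject fit (linear kernel
keeps them interpretable); each network's share is its fraction of total
absolute weight.

## Synthetic-data generator

Nodes carry a latent axis g ∈ [−1, 1] split into 7 contiguous blocks
labeled with the canonical network names, VN at the primary end through DMN
at the transmodal end. Time series mix 6 shared latent sources whose
loadings are Gaussian bumps along the axis (width τ = 0.3), a per-block
signal (weight 0.1) and white noise (SD 0.5), so expected node–node
correlation decays with |g_i − g_j| with added within-network structure.
Each subject's axis is additionally jittered per network block by a factor
N(1, 0.06) — inter-individual differences in gradient organization, without
which subject-level gradient features would be pure estimation noise and
outcome prediction from them ill-posed. These structural constants were
fixed once so that the group-mean connectivity embeds to a first gradient
correlating |r| > 0.9 with the planted axis while network-specific
individual variability remains recoverable; they are exposed as arguments. In cases, the axis is rescaled
by the compression factor on the affected nodes (|g| > 0.6, the extremes),
contracting the recoverable gradient range — compression 1 plants nothing
and serves as the null generator for every calibration suite. Ages and
sexes are drawn identically in both groups (balance improves with n);
clinical scores are integer-rounded with the positive-subscale floor at 7.

Post-treatment scores drop by a mean treatment response (default 4 points)
plus a planted linear function of baseline gradient features whose weights,
when used in demonstrations, are sized so the planted response spread is
about twice the baseline score spread (a moderate, recoverable effect).

Expression: planted genes are coupling·standardize(zmap) + noise; remaining
genes are AR(1)-smoothed noise along the region ordering — a cheap stand-in
for spatial autocorrelation that does not respect true 3-D geometry, one of
the ways the generator is simpler than real data. Post-treatment scores
subtract a planted linear function of baseline gradient features; the
linear term is centered across treated subjects (the generator's intercept
choice) so strong planted weights move scores around baseline instead of
clipping everyone to the scale floor, then rounded and clipped to the
instrument range.

What the generator does **not** emulate: volumetric geometry and smoothing,
hemodynamics, motion artifacts beyond an FD column, realistic gene-gene
coexpression modules, hemispheric asymmetries. Passing tests therefore
demonstrate the statistical machinery (calibration, recovery, determinism),
not robustness to those real-data complications.

## Problem sizes and determinism

Calibration suites run at reduced sizes chosen for the package's test
budget: GLM/cluster calibration on 200 null cohorts of 15/group × 60 nodes;
spin calibration at 150 parcels × 1000 spins × 200 repetitions; PLS
recovery at 100 regions × 500 genes × 1000 bootstraps. The
planted-compression direction check runs the full 100 cohorts at 50/group ×
200 nodes. Every random operation takes an explicit seed; the end-to-end
pipeline writes a manifest of config plus SHA-256 of every output, and two
runs with the same config are byte-identical.

## Known limitations

- The expression generator's AR(1) spatial autocorrelation is indexed by
  region order, not true distance on the sphere.
- Nearest-neighbor spin reassignment duplicates some parcels (logged rate on
  synthetic spheres ≈ 10%).
- Spearman spin nulls reuse the rank vector of the unpermuted map; exact
  re-ranking of duplicated assignments would differ negligibly.
- No weighted-graph topology, no vertex-level spins, no volumetric I/O.
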