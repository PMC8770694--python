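# Methods

This note documents the models and numerical choices behind `craniomorph`,
what its synthetic data do and do not emulate, and the design decisions
taken where the standard literature leaves room.

## Superimposition

GPA is full Procrustes superimposition into shape space: each
configuration is translated to its centroid, scaled to unit centroid size
(CS = root of summed squared landmark distances from the centroid, in mm;
log CS is the "size" variable used everywhere downstream), and rotated to
the running consensus by orthogonal Procrustes with the determinant
constrained to +1 (reflections are never introduced; the SVD sign of the
last singular vector is flipped when needed). The consensus is re-centered
and re-scaled to unit CS each iteration. Iteration stops when the squared
consensus displacement falls below 1e-24 (at most 200 iterations; typical
datasets converge in well under 10). The tolerance is deliberately far
below visual precision: it makes alignments — and hence all pairwise
Procrustes distances — reproducible to < 1e-8 under arbitrary rotation,
translation and rescaling of the raw input, which the test suite checks
over 100 randomized trials.

Aligned coordinates are used directly as Euclidean tangent-space
coordinates; no separate orthogonal projection is applied. This is the
usual working assumption when shape variation is small relative to the
consensus, and is a documented limitation for datasets with extreme shape
ranges.

Missing landmarks are estimated before GPA with a 3D thin-plate-spline
interpolant (radial basis interpolation with the thin-plate kernel and a
degree-1 polynomial tail, so affine relations between reference and target
are reproduced exactly). The reference form is the consensus of complete
conspecific specimens when any exist, otherwise the complete-specimen
consensus of the whole sample; the estimation needs at least four
non-coplanar observed landmarks, and coplanarity is detected from the
singular values of the centered anchor set. Estimated landmarks are
recorded on the configuration (`estimated_landmarks`, 1-based) so
provenance survives the cleared missing mask.

Landmark numbering is 1-based everywhere user-facing (labels, error
messages, module schemes, the one-sided subset defined as "delete
landmarks 23–44") and 0-based in arrays.

## Linear models (RRPP)

`rrpp_lm` fits multivariate linear models by least squares with
sequential (Type I) sums of squares and permutation inference by residual
randomization: for each term, the reduced model containing all preceding
terms is fitted, its residual rows are permuted and added back to its
fitted values, and the term's F statistic is recomputed; the P-value is
the proportion of the permutation distribution (observed statistic
included, so min P = 1/(n_perm+1)) at or above the observed value. The
effect size Z is the standardized deviate of log F within that
distribution. Default 999 permutations; the generator seed is recorded in
every fit. One permutation schedule is shared across terms.

pgls mode transforms response and design by P = Λ^(−1/2)Eᵀ from the
eigendecomposition C = EΛEᵀ of the Brownian covariance (shared root-to-tip
path lengths) implied by a dated tree, making BM errors exchangeable. On a
star phylogeny with equal branch lengths the transform is a scalar, so ols
and pgls coincide exactly — a property test. Categorical predictors use
treatment contrasts with the alphabetically first level as reference;
group summaries are reported as LS means, not raw coefficients. Designs
are checked term by term: a term that fails to raise the design rank by
its column count is reported by name as aliased.

Pairwise follow-ups reuse the fitted model: group LS means (other
predictors at their design means) compared by Euclidean distance, or —
for group × continuous interactions — per-group slope vectors compared by
length difference and angle. The null permutes the residuals of the model
without the grouping term (for means) or without the interaction (for
slopes).

## Phylogenetic signal, disparity, rates

Multivariate Blomberg's K generalizes the univariate statistic over
dimensions: K = (SSE₀/SSE_C) / E_BM, with SSE₀ the Euclidean sum of
squared deviations from the GLS mean, SSE_C the phylogenetically corrected
(C⁻¹-weighted) sum, and E_BM = (tr C − n/(1ᵀC⁻¹1))/(n−1) the Brownian
expectation of that ratio. K ≈ 1 under BM; significance comes from
permuting species across tips. Note the statistic's known sensitivity to
tip-level noise: with many short terminal branches even ~10% intraspecific
variance pulls K well below 1, which is visible in the synthetic examples
and mirrors the depressed K values typical of real cranial data.

Disparity is the Procrustes variance — mean squared shape-space distance
of group members from the group mean — with pairwise absolute differences
tested by permuting group labels. Singleton groups are excluded with a
warning. Caveat: when groups are clades, members share inherited
deviations and label permutation is anticonservative; clade-level
disparity contrasts should be read descriptively.

Evolutionary rates: the net multivariate BM rate of a group is the mean
squared phylogenetically transformed tip deviation (rows of
C^(−1/2)(Y − 1âᵀ)) summed over dimensions. The max/min rate ratio is
tested against a parametric null — BM with the pooled rate simulated on
the same tree — rather than tip permutation, which would destroy the
tree–data covariance the statistic depends on. The null assumes pure BM;
added specimen-level noise loads hardest on short-branch clades and can
inflate the ratio, a misspecification the synthetic examples demonstrate.

The regression score projects centered shape rows onto the normalized
multivariate regression coefficient of shape on a continuous predictor: a
univariate summary maximally associated with that predictor, invariant to
rotations of the shape basis.

## Modularity

All modularity statistics run on the 31-landmark one-sided subset.
The covariance ratio for a module pair is ‖S₁₂‖_F over the geometric mean
of the within-module norms with the variance diagonal removed; multi-module
CR averages over pairs. The permutation null reassigns whole landmarks
(their three coordinates together — coordinates of one landmark are not
exchangeable) to modules of the same sizes; Z is the standardized observed
CR (negative = more modular than chance) and P the fraction of null values
at or below it. Phylogenetic CR computes the same quantity on independent
contrasts, whose cross-products are taken about zero (contrasts have
expectation zero by construction); on a star phylogeny this reduces
exactly to the non-phylogenetic CR.

EMMLi-style comparison models the Fisher-z-transformed association
coefficients as Normal(z(ρ), 1/(N−3)) with one ρ per block and N = the
number of landmarks as effective sample size. The block MLE is closed-form
(inverse Fisher transform of the mean z; verified against a grid-search
oracle). For each scheme, a single-ρ, a within+shared-between, and a
fully separate block model are scored and ranked by AICc (sample size =
number of coefficient pairs); the correlation between log-likelihood and
parameter count across models is reported as a diagnostic, since heavily
parameterized schemes tend to win on likelihood alone.

Module discovery clusters the rows of an association/distance matrix with
k-means (25 restarts per k by default) and chooses k by the gap statistic
with B = 100 reference sets, uniform over the principal-axis-aligned
bounding box of the data (the rotated reference of the standard gap
implementation; an axis-aligned box fails badly on the strongly
anisotropic rows of a distance matrix). Chosen k is the smallest with
Gap(k) ≥ Gap(k+1) − SE(k+1). Schemes containing modules of fewer than two
landmarks are flagged and rejected by CR/EMMLi as not biologically
meaningful. The five shipped anatomical schemes (two-module
face/neurocranium, tripartite, four-module, nine-module per-element, and a
six-region mammalian scheme) are defined as editable region → module maps
over the template's anatomical regions, because landmark-by-landmark
membership is study-specific.

## Ecology

Occurrence tables are long-format (cell × species) with habitat class and
NPP per cell. Filtering keeps cells with ≥ 4 species and habitat classes
with strictly more than 40 such cells. Faunal lists rank species within
each habitat by occupied-cell count; the top-fraction cut is inclusive at
ties (every species tied with the cutoff rank stays), which makes the
lists independent of input row order. NPP bins are equal-count quantiles;
the published edge set (0/115/320/580/1100, trillions kg C per cell) ships
as a constant for use with the original raster extraction, while synthetic
runs compute their own quantile edges. The joined covariate table
duplicates species across categories by construction and therefore carries
a flag that makes pgls fits fail with an explanatory error; ols is the
correct model there.

## Synthetic data

The generator's defaults are the study conditions: 96 species on a Yule
tree rescaled to a 15-Myr root (the approximate crown age of the clade),
141 specimens (a seeded choice of 45 species receives a second specimen),
53 landmarks on a bilaterally symmetric schematic cranium (22 right-side,
22 mirrored left, 9 midline) whose regions make the one-sided subset, the
facial-length landmarks (5, 13, 52) and the anatomical module schemes
meaningful. Log centroid size evolves by univariate BM (tip SD ≈ 0.5 around
log 150 mm, spanning dik-dik- to buffalo-sized skulls); shape evolves by
multivariate BM in the template's tangent space with per-coordinate tip SD
≈ 0.01 shape units; the allometric axis (facial elongation with a dropped
rostrum) is projected into the shape tangent space — its translation,
rotation and scale components would otherwise be silently removed by
superimposition — and planted with strength 0.08 shape units per log-size
unit, which puts the size effect near a tenth of shape variance, the
magnitude typical of strongly allometric cranial data. Intraspecific plus
measurement noise is 0.003 shape units per coordinate (≈ 9% of
interspecific variance, comfortably "smaller than between-species
differences"). Optional modular covariance plants uniform within/between
landmark correlations block-wise. Finished configurations are randomly
rotated, translated and rescaled before being handed to the readers, so
superimposition is genuinely exercised end to end; all randomness flows
through one seeded generator, and equal seeds give bit-identical datasets.

What the generator does not emulate: realistic cranial anatomy or
landmark-specific error variances, sexual dimorphism in shape (sex is a
metadata flag only), scan-type artifacts (scan type is assigned but never
influences coordinates), non-Brownian evolution (no OU, no rate shifts),
and spatially autocorrelated "integration" beyond the planted block
structure. Passing tests therefore establish that the statistics are
calibrated and recover planted effects under their own assumptions — not
that real crania satisfy those assumptions.

## Problem sizes and defaults in tests

The calibration suite uses the sizes that keep a full run in the order of
a minute: 100 BM replicates for the K calibration; 1000 null simulations
at n = 50 with 199 permutations for the type-I error of RRPP; 50
replicates each for planted-modularity (n = 96, within ρ 0.7 / between
0.1) and gap-statistic recovery (B = 40, 10 restarts); 999-permutation
defaults remain on the public API. Allometry recovery checks monotone R²
across planted strengths 0.04/0.08/0.16 and a < 15° angle between fitted
and planted axes at the strongest setting, where estimation noise is small
relative to signal.

## Known limitations

- Tangent-space approximation without projection (above).
- Label-permutation nulls for disparity and modularity contrasts ignore
  phylogenetic dependence of clade-defined groups.
- The rate-ratio null is exact only without specimen-level noise.
- EMMLi's effective sample size is a convention, not an estimate; its
  AICc ranking inherits the parameter-count affinity the diagnostic
  correlation exposes.
- The anatomical module schemes ship as template-region defaults and are
  meant to be edited to a real study's landmark definitions.
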