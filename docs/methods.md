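# Methods

This note documents the models, conventions and design choices behind
cereconn, in the spirit of a package methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Connectivity construction

For each subject and N-back condition, the R × R matrix of pairwise Pearson
correlations between ROI time series is variance-stabilised with Fisher's
r-to-z (arctanh), with |r| clipped at 1 − 1e-7 so duplicated series cannot
produce infinities.  The diagonal is zeroed.  Sparsification keeps entries
whose |z| is at or above the 85th percentile (linear interpolation) of the
**absolute off-diagonal values** — both triangles, i.e. every unique value
counted twice.  This convention is pinned because it makes edge counts
exactly reproducible: a 165-ROI matrix with distinct values always retains
2030 of its 13530 unique edges (15.004%).  Because the duplicated pairs
make the interpolated percentile land exactly on an attained value, the
boundary edge is retained (comparison is ≥ cutoff).  Surviving edges keep
their sign; sign-preserving retention matters because the network-level
features average signed weights.  `pearson_matrix` explicitly symmetrizes
the correlation matrix: BLAS matrix products are not bit-symmetric, and a
one-ulp asymmetry is enough to break the exactly-duplicated-pair property
the percentile convention relies on.

Motion QC follows the framewise-displacement rule: a subject is excluded
when the proportion of volumes with FD > 0.5 mm reaches 20%.  The boundary
is inclusive (exactly 20% excludes) — the conservative reading of an
otherwise ambiguous rule.

## Graph metrics

Nodal strength is the sum of absolute incident weights.  Local clustering
is the Onnela geometric-mean weighted form (as implemented in networkx) on
|w| rescaled by the graph's maximum |w|; isolated and degree-1 nodes score
0.  Network-level features for K networks:

* `Inter_km`: the mean signed weight over all |N_k|·|N_m| ordered ROI pairs
  between networks k and m.  Self-pairs (k = m) are included in the feature
  set — this is what brings the inter-network block to K(K+1)/2 = 21
  features for K = 6 and the total to 33.  For a self-pair the zero
  diagonal is inside the average, so `Inter_kk = Intra_k · (|N_k|−1)/|N_k|`;
  the redundancy with `Intra_k` is accepted to keep the 33-dimensional
  feature space.
* `Intra_k`: the mean signed weight over the |N_k|(|N_k|−1)/2 unique
  within-network pairs.  (A published form of this denominator mixes the
  two network indices and double-counts relative to a j > i summation;
  the unique-pair mean is the only reading under which `Intra` is a mean
  connectivity, and it is what this package computes.)
* `ND_k = Σ_{m≠k} Inter_km`: the network's total integration with the rest
  of the connectome; the self-pair is excluded by definition.

## Contrast statistics

Group comparisons use Welch's unequal-variance t-test with
Welch–Satterthwaite degrees of freedom and two-sided p-values.  Cohen's d
uses the classic pooled SD with (n₁−1, n₂−1) weighting and no small-sample
(Hedges) correction.  FDR control is Benjamini–Hochberg, applied within a
declared family; the default family is condition × contrast × feature class
(e.g. the 21 inter-network tests at one condition for one contrast), with a
condition × contrast alternative (`family="all"`), which is also the rule
used for ROI-level families.  The four familial contrasts are
SCZ:CON (manifest illness), SCZ:SCZ-SIB (clinical state within shared
genetics), SCZ-SIB:CON-SIB (genetic liability without psychosis), and
CON:CON-SIB (shared-environment control).

`anova_eta` computes one-way ANOVA F and partial η² = SSB/(SSB+SSW)
directly from group summary statistics (n, mean, SD) so published summary
tables can be re-analysed without subject-level data.  `fisher_exact_2x2`
is the standard two-sided hypergeometric test and refuses zero margins.

## Composite score and ROC

The composite is `Σ_j value_ij · |d_j|` over the inter-network features
passing q < 0.05 for the chosen contrast and condition, applied to raw
feature values (no z-scoring).  Weights may be estimated in-sample (the
real-data pathway; optimistic at small n) or planted (the simulation
pathway used for calibration).  AUC is the Mann–Whitney rank estimator with
midrank ties, numerically identical to the trapezoidal area under the
empirical ROC curve; orientation is chosen so AUC ≥ 0.5 and the flip is
recorded.  The 95% CI is a stratified percentile bootstrap (B = 2000,
seeded) — distribution-free and reproducible.  The Youden threshold
maximizes sensitivity + specificity − 1 with ties broken toward higher
specificity (a documented, arbitrary choice).

Under the bivariate-normal calibration model (unit variances, correlation
ρ, mean shifts Δ, weights w) the composite difference between groups is
Gaussian, giving the closed-form AUC Φ(wᵀΔ / √(2·wᵀΣw)); with the default
planted effects (1.547, 1.155) and ρ = 0.25 this is ≈ 0.890, which the
simulation protocol reproduces.

## Subtype clustering

Clinical-cognitive features (20 by default: SAPS/SANS global scores, four
SAPS and five SANS domain scores, nine cognitive scores) are min–max
normalized to [0, 1] after listwise deletion of incomplete rows.  Symptom
columns use the theoretical 0–5 rating-scale bounds; cognitive columns use
the observed complete-case range, unless a table declares explicit bounds
(the synthetic generator does, making normalization exact).  The feature
list is configuration-driven, not hard-coded.

PAM (k-medoids) is BUILD followed by best-improvement SWAP on Euclidean
dissimilarity.  Two engineering details matter for correctness: SWAP
accepts equal-cost sideways moves to unvisited medoid sets (cost plateaus
frequently separate swap-local optima from the global optimum), and the
descent is restarted from four seeded random initial sets in addition to
BUILD, keeping the best final cost.  The result is deterministic given data
and seed, and matches exhaustive medoid search on all tested instances with
n ≤ 8.

Consensus clustering runs PAM on 100 subsamples of 80% of subjects
(without replacement, optional pluggable embedding — identity by default;
a UMAP-style reducer can be injected, but the consensus machinery is
embedding-agnostic).  consensus[i,j] is the co-assignment count divided by
the co-sampling count; pairs never co-sampled are undefined, logged, and
excluded from PAC.  Final labels come from PAM on (1 − consensus).  PAC is
the fraction of defined off-diagonal entries strictly inside (0.1, 0.9).
Partition non-randomness is tested by independently permuting each feature
column (destroying inter-feature structure, preserving marginals) and
comparing the Calinski–Harabasz statistic of PAM at k, with the add-one
p-value convention (1 + #{null ≥ obs}) / (1 + B), default B = 10000.

**Number of subtypes.** k over 2..6 is chosen by minimum PAC.  Ties are
real: on well-separated data several k reach PAC = 0 (a k−1 merge of two
separated clusters is also perfectly stable).  Among PAC-tied candidates
the silhouette is systematically biased toward merging an intermediate
cluster into a neighbour — exactly the geometry of an intermediate subtype
— so ties are broken by the higher Calinski–Harabasz index instead
(silhouette is still reported), then by smaller k.  When even the best PAC
exceeds 0.5 the result is flagged "no stable k".

## Synthetic cohort generator

The generator defines the study conditions; its defaults are not tuning
knobs.  Groups default to SCZ 23, SCZ-SIB 34, CON 20, CON-SIB 21; three
load conditions; 165 ROIs in six networks (DMN 34, FP 21, CO 32, SM 33,
OCC 22, CER 23 — a six-network split of a standard 160-region functional
parcellation rescaled to 165); T = 137 volumes at TR 2.5 s.

*Time-series mode* draws each subject × condition series from a zero-mean
multivariate normal whose correlation matrix has within-network off-diagonal
0.3, between-network 0.1, and group × condition block deltas that mirror
the planted pattern (largest CER-SM deficit at 1-back; a CER-CO deficit at
1-back; smaller CER-SM deficits at 0- and 2-back; a positive CER-DMN shift
at 0-back).  Non-positive-definite block structures are projected by
eigenvalue clipping at 1e-6 with diagonal renormalization (iterated; the
output minimum eigenvalue is ≥ 1e-6 or an error is raised).  Observation
noise (`noise_sd`) defaults to 0 so block correlations are exactly the
targets; note that a cross-block correlation above the within-block level
is infeasible (non-PD) and will be shrunk by the projection.  FD traces are
log-normal: median 0.12 mm (σ = 0.4) for ordinary subjects and 0.6 mm
(σ = 0.3) for a high-motion fraction (default 0.12, emulating the observed
attrition from a raw cohort to subjects with usable data), which reliably
trips the exclusion rule.

*Direct-feature mode* draws 33-feature vectors from an equicorrelated
(ρ = 0.25 by default; the real between-feature correlation is unknown, so
ρ is an explicit simulation parameter) unit-variance Gaussian in which
contrasted groups differ by exactly the planted standardized amounts
(defaults: CER-SM −1.547 and CER-CO −1.155 at 1-back and −1.078/−0.914 at
0-/2-back for SCZ vs CON, CER-DMN +0.726 at 0-back, and CER-SM −1.086 for
SCZ vs SCZ-SIB — a state effect with no SCZ-SIB vs CON-SIB trait effect).
Effects are planted on the post-metric feature scale, not the covariance
scale, so recovery tests are free of the nonlinear covariance→metric
mapping.  Pairwise constraints are resolved sequentially into group means
(reference mean 0), erroring on conflicts.

*Clinical mode* draws each subject's subtype from mixing proportions
(36:29:33)/98, features as subtype centroid + Gaussian noise
(σ = 0.05 by default) clipped to [0, 1], and the diagnostic group label
from the subtype's composition (subtype 1: 56% CON / 44% CON-SIB;
subtype 2: 79% SCZ / 21% SCZ-SIB; subtype 3: 29/29/21/21).  Centroids are
midpoints of the characteristic ranges of each profile (e.g. subtype-1
cognition 0.625, symptoms 0.05; subtype-2 vocabulary 0.375, affective
flattening 0.65; subtype-3 intermediate 0.45 with working-memory sparing at
0.525); features without a characteristic value get profile-consistent
interpolations.  Symptom columns are emitted on the raw 0–5 scale with
declared bounds; every symptom column (global and domain) is treated as a
0–5 mean-rating scale.  The true subtype is returned separately and never
enters the analysis path.

## What the simulations do and do not show

The generators produce stationary Gaussian series with exact block
correlation structure — no hemodynamic convolution, task-event timing,
scanner drift, physiological noise, or spatial autocorrelation — and
clinical features with spherical within-subtype noise.  Passing tests
therefore demonstrate that the pipeline's statistics recover known
structure under its own model assumptions (correct implementation and
calibration), not that real fMRI cohorts satisfy those assumptions.
Real-data idiosyncrasies (motion artefact correlated with diagnosis,
site effects, non-Gaussian symptom distributions, missingness that is not
completely at random) are out of scope.

## Problem sizes and numerical choices

Calibration protocols use 200 replicates at n = 1000/group for effect-size
recovery, 2000 replicates for the composite AUC, and 50 seeds for subtype
recovery at n = 98 — sizes chosen so Monte-Carlo error is well below the
quantities' precision while the full suite runs in minutes on one core.
Ties in PAM break toward the lowest index / lexicographically smallest
medoid set; BH q-values are computed by statsmodels; Welch statistics by
scipy; silhouette, Calinski–Harabasz and ARI by scikit-learn.  All
randomness flows from explicit integer seeds via `numpy.random.SeedSequence`
fan-out, so every stage is independently reproducible.

## Known limitations

* The thin ROI-TSV adapter is untested against any real released dataset;
  image-level preprocessing is explicitly out of scope.
* In-sample composite weighting is optimistic at n ≈ 40; the package
  provides planted-weight and in-sample modes but no cross-validation.
* PAC-based k selection is reported with a single subsampling scheme
  (80%, 100 iterations); the consensus literature shows sensitivity to
  these choices, which are exposed in configuration but not swept.
* The permutation test permutes columns independently, which preserves
  marginals but not any null dependence structure one might wish to keep.
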