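# Methods

This note documents the models, estimators and design choices behind
`edgentropy`, and what the synthetic-data experiments do and do not
establish.

## Edge-centric networks and nodal entropy

For a region × time BOLD matrix, each region's series is z-scored with the
*population* (divide-by-T) standard deviation. With that convention the
edge time series `e_mn(t) = z_m(t) z_n(t)` satisfies
`mean_t e_mn = Pearson r(m, n)` exactly, which the test suite enforces to
1e−10; the sample-SD convention would only satisfy it up to a factor
(T−1)/T.

Edges (the N(N−1)/2 upper-triangle pairs, row-major order) are clustered
by K-means on their raw time courses — Euclidean distance, k-means++
initialization, 300 iterations max, tolerance 1e−4. Defaults are k = 10
communities and 25 restarts; the restart with the lowest within-community
sum of squares wins, ties resolved to the earliest restart so runs are
reproducible. All restart SSE values are kept on the result and logged at
debug level.

Each region's community profile is the label distribution of its N−1
incident edges; dividing the incident-edge counts by N−1 is the only
normalization that makes the profile a probability vector. Nodal entropy
is the Shannon entropy of that profile in bits, normalized by log2 k so
that values live in [0, 1] (with 0·log 0 = 0 and the k = 1 case defined as
0). The normalization base is exposed as a parameter: normalizing by the
number of subnetworks (7) instead of communities is a defensible
alternative reading, and is a monotone rescaling that leaves every rank
statistic in this package unchanged. Global and subnetwork entropies are
plain means over regions; the identity "global = subject-size-weighted
mean of subnetwork means" is a test invariant.

Clustering is per subject by default: each subject's edge communities are
estimated from their own eTS, which keeps memory bounded and matches the
subject-level entropy phenotype. A `clustering_scope="group"` mode fits
one set of centroids on the pooled edge rows of all subjects and labels
each subject's edges against those shared centroids, making community
identities comparable across subjects at the cost of a much larger
clustering problem.

Confound removal (sex, age, years of education) defaults to OLS
residualization of the subject-level entropy features, with the fitted
intercept added back so group means under null covariates are preserved;
residuals are orthogonal to each covariate by construction. A literal mode
that residualizes every (region, timepoint) BOLD value across subjects
before the edge pipeline exists behind a flag (it requires equal scan
length); the feature-level default is the statistically conventional
choice and avoids re-clustering artifacts.

## Group statistics

Global plus the 7 subnetwork entropies are compared across the three
groups with Kruskal–Wallis (tie-corrected; the all-tied degenerate input
is defined as H = 0, p = 1), BH-FDR across those 8 tests in one family.
Measures passing FDR < α (default 0.05) get the three pairwise
Mann–Whitney U tests — exact null when the smaller group has ≤ 8
observations without ties, normal approximation with tie and continuity
correction otherwise — BH-corrected across all post-hoc p values as a
second family. Pearson correlations between FDR-significant subnetwork
entropies and behavioral scores are computed within each patient group and
BH-corrected within that family. The three-family structure is the
minimal reading of a three-step analysis plan; nothing in the code depends
on it beyond which p values share a correction.

The per-region contrast feeding the transcriptome stage is a
pooled-variance two-sample t (MDDSI minus MDDNSI direction). The Student
rather than Welch form is deliberate: group sizes are mildly unbalanced,
and only the relative spatial pattern of the map matters downstream.

## Classification

Binary linear-SVM classification of nodal-entropy vectors with recursive
feature elimination (importance = squared SVM coefficients, one feature
dropped per iteration). All selection and tuning happen inside each
training fold of a stratified 5-fold split: RFE first (at C = 1), then a
grid search over C ∈ {0.01, 0.1, 1, 10, 100} by inner 3-fold accuracy.
Metrics (accuracy, precision, recall, F1, in percent) are averaged over
the held-out folds. A no-leakage property is tested: shuffling held-out
labels cannot change training-fold selections. A `rfe_scope="global"`
mode (one RFE on all data before CV) exists for comparison with
single-selection protocols but is optimistic and not the default. Feature
stability is summarized by selection frequency across folds, ties broken
by mean |coefficient| then region index. No class weighting is applied by
default; a balanced mode is available.

## Connectome–transcriptome association

Gene expression columns are standardized and the response map centered
inside `fit_pls` (PLS weights are scale-sensitive; the expression matrix
is assumed pre-normalized per gene but is re-standardized regardless).
The PLS fit itself is NIPALS (via scikit-learn) with 15 components by
default. Per-component explained response variance is computed from the
mutually orthogonal score vectors as r²(t_a, y); for a univariate response
the first weight vector has the closed form X'y/‖X'y‖, which the tests use
as an independent oracle. PLS1 is reported with its scores oriented to
correlate non-negatively with the response — a pure reporting convention,
recorded on the result object, under which "PLS1+" genes are those whose
expression tracks the response map positively.

PLS1 significance comes from a permutation test on its explained response
variance, p = (1 + #{surrogate ≥ observed}) / (1 + n_perm). When a
region–region distance matrix is available, surrogate maps are
variogram-matched randomizations: the map is permuted, kernel-smoothed at
several candidate bandwidths (Gaussian kernels at 0.1–1.0 of the maximum
distance), and affinely rescaled so its empirical variogram (20
equal-count distance bins) best matches the original's; the
best-fitting bandwidth wins and the achieved variogram mismatch is
exposed for diagnostics. This preserves the spatial autocorrelation that
makes plain permutation anticonservative for smooth brain maps — a
property the test suite demonstrates directly. Without a distance matrix
the test falls back to plain region permutation, which is exactly
calibrated when the response is exchangeable.

Gene-weight uncertainty is estimated by bootstrap over regions (default
1,000 resamples; degenerate resamples with a constant response are redrawn
and counted). Each resample's PLS1 weight vector is sign-aligned to the
original by their inner product, and gene g's corrected weight is
Z_g = w_g / SD_boot(w_g). "Strongly positive/negative" gene sets are
defined as two-sided normal p values from Z under BH-FDR < 0.05, split by
sign and ranked by |Z| — the threshold is a parameter, since the original
analysis named neither formula nor cutoff. Cell-type enrichment of a gene
list is a permutation test drawing random lists of the same size from the
background universe, BH-corrected across the 7 cell classes; on a small
fixed construction the permutation p agrees with the exact hypergeometric
tail within Monte-Carlo error.

## Synthetic data

The generator is the package's ground-truth instrument, not a fixture.
Each subject's signal is `x_r(t) = Σ_s w̃_rs c_s(t) + ε(t)` with:

- **Mixing weights** `w_r ~ Dirichlet(α_r · 1)` over 8 latent modules;
  per-region concentrations are log-uniform over [α/10, 10α] around
  α = 0.5, giving planted normalized mixing entropies that span ~0.1–1.0.
  Rows are rescaled to unit norm in the signal sum so sparse and uniform
  regions see the same SNR. The planted entropy of region r is the
  normalized Shannon entropy of w_r — the quantity nodal entropy should
  recover in rank.
- **Latent module signals** that are piecewise-stationary across 8
  equal-length temporal states: in each state one module's amplitude is
  boosted (×4) and the others damped (×0.3), and one random module pair is
  correlated (|ρ| ∈ 0.2–0.5). The state-salient amplitude structure is
  what makes edge communities align with modules: with
  temporally homogeneous modules, edge clusters form around module *pairs*
  and a region's label diversity is dominated by its partners' memberships
  rather than its own, capping the achievable entropy recovery well below
  what the planted structure permits (with 4 undamped modules the
  estimated entropy saturates near 0.7 and rank recovery tops out around
  0.75–0.84; the 8-module salient-state design reaches ≥ 0.82 with a
  perfect-labeling ceiling of ≈ 0.95). This is also why the module/state
  count defaults to 8 rather than a smaller value.
- **Noise** ε i.i.d. Gaussian (SD 0.5) with an optional AR(1) coefficient
  (default 0 — the temporal autocorrelation of real BOLD is not asserted,
  only supported).
- **Group effects** as additive shifts on the log-concentration of regions
  in targeted subnetworks, so e.g. a −2 shift on dorsal-attention regions
  lowers their expected mixing entropy in that group.
- **Covariates** (sex, age, education) with group-specific distributions
  patterned on a three-group clinical cohort (n = 98/60/90 by default),
  leaking weakly (2% amplitude scaling) into the signal so residualization
  is exercised, plus a behavioral score constructed to correlate at
  r = −0.5 with the planted entropy of a target subnetwork.
- **Expression maps**: 3-D random region coordinates, Gaussian-process
  noise with an exponential kernel (length scale 0.3), 10 of 200 genes
  additionally carrying 1.5× the standardized target map (the planted
  group-difference map in the cohort pipeline); all columns standardized.

All generators are bit-reproducible: every stream derives from
(config.seed, purpose, counter) tuples, so subjects are independent but
jointly reproducible, and cohort-level structure (state couplings, base
concentrations) is shared across subjects.

What passing on this data shows: that the estimators recover the specific
planted structure — mixing-entropy ranks, subnetwork mean shifts, signal
genes — at realistic SNR, and that the inferential machinery is calibrated
(type-I ≤ nominal, permutation p uniform under the null). What it does not
show: robustness to head motion, physiological noise, haemodynamic
convolution, parcellation error, or donor-sampling artifacts of real
expression atlases — none of which are modelled.

## Problem sizes and numerical choices

Monte-Carlo checks run at reduced size chosen to keep the full suite
around a minute of compute per check: calibration/power cohorts use 30
regions × 120 time points, 15 subjects/group, 5 K-means restarts and 20
replicates; permutation calibration uses 100 replicates at n_perm = 200.
The headline recovery checks (entropy recovery, gene recovery) run at the
full default configuration (50 regions × 440 time points, 25 restarts;
200 genes). Degenerate inputs fail loudly and early: constant regions,
rank-deficient covariate designs, constant expression columns and
inconsistent label sets all raise with the offending names. Ties in
min-SSE restart selection and in feature-frequency ranking are broken
deterministically (earliest restart; larger mean |coefficient|, then lower
index).

## Known limitations

- Edge K-means on raw (unstandardized) edge rows is magnitude-sensitive;
  high-amplitude edges can split clusters by amplitude. This follows the
  standard protocol but contributes most of the gap between achieved
  (~0.85) and ceiling (~0.95) entropy-rank recovery.
- The variogram surrogate generator matches the binned empirical
  variogram, not the full spatial covariance; its null is approximate,
  though demonstrably more conservative than plain permutation for smooth
  maps.
- The classification stage reports ROC points per fold but no pooled ROC
  summary; per-fold metrics are the contract.
- With very small groups the exact Mann–Whitney path requires tie-free
  data; tied small samples fall back to the corrected normal
  approximation.
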