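# Methods

`covnet` implements a covariate-specific differential-network analysis
for serum metabolomics cohorts: given a samples × features concentration
table (small-molecule metabolites plus lipoprotein fractions and
sub-fractions) and a samples × covariates clinical table for two groups
(e.g. women and men), it extracts the part of each feature associated
with each clinical covariate, infers one association network per
covariate and group, tests per-feature differential connectivity between
groups, and summarises the whole collection of networks with a
simultaneous component decomposition. This note records the models, the
defaults, and the design choices where the method description leaves
room.

## Data preparation

Clinical covariates with 25% or more missing entries are dropped (the
bound is strict: a column with exactly 25% missingness is removed).
Remaining gaps are filled with an iterative random-forest imputer in the
missForest style: columns are visited in order of increasing
missingness; each incomplete column is regressed (continuous) or
classified (dichotomous) on all other columns with a 100-tree forest
trained on its observed rows; the sweep repeats until the normalised
change in the imputed values stops decreasing, up to 10 iterations, and
the last improving iterate is returned. Observed cells are never
modified and dichotomous columns are imputed in {0, 1}. The imputer is
seeded and deterministic.

All continuous variables are natural-log transformed. Dichotomous (0/1)
covariates pass through unchanged: log(0) is undefined and a monotone
transform of a binary indicator carries no information, so a blanket
log-transform cannot literally include them. An additive offset is
available for concentration tables containing exact zeros; the default
offset is 0 and nonpositive values raise an error naming the column.
Because the network stage uses Spearman correlation, the log transform
does not change any correlation among continuous features — it matters
only for the regression-based extraction stage. Flagged samples are
excluded by an explicit ID list in the configuration.

Imputation is run on whatever table it is given; the pipeline imputes
each group's covariates separately because every downstream analysis is
group-specific (a pooled-imputation variant is a one-line change at the
call site).

## Covariate signal extraction

For target covariate x_m and feature p the model is

    y^(p) = b^(p) x_m + Σ_{j≠m} e_j^(p) (x_m ∘ x_j) + (other main effects) + ε,

with all covariates z-scored before products and interactions restricted
to first order with x_m. The fit regresses y^(p) on the full design (M
main effects plus the M−1 interaction columns, about 2M−1 columns); the
extracted signal ŷ^(p) is the fitted contribution of the x_m-involving
terms only, which isolates the covariate-specific part of the feature
while implicitly adjusting for the other M−1 covariates. Constant
design columns are dropped with a warning.

With M ≈ 100 covariates and a few hundred samples the design is near- or
under-determined, so the default estimator is lasso-penalised least
squares with the penalty chosen by 10-fold cross-validation (seeded
folds). An unpenalised least-squares mode exists for small well-posed
problems and raises on rank deficiency rather than silently
pseudo-inverting. The extracted signal always lies in the span of
{x_m, x_m ∘ x_j}, a property asserted in the tests. Extraction is run
within each group separately, since all downstream networks are
group-specific.

## PCLRC network inference

Association networks are inferred with PCLRC (Probabilistic Context
Likelihood of Relatedness on Correlation). For each of `n_iterations`
(default 1000) rounds, 75% of the samples are drawn without replacement,
a Spearman correlation matrix is computed (average ranks for ties;
constant columns get zero correlation with a warning), and CLR
background scores are formed on s = |R|: for edge (i, j),
z_i = max(0, (s_ij − μ_i)/σ_i) against row i's off-diagonal background,
symmetrised as √(z_i² + z_j²); a zero-variance background yields z = 0.
The top 30% of edges by CLR score are marked (ties at the cutoff are all
included; zero scores are never marked, since a zero CLR score carries
no evidence). The per-edge marking frequency is the edge-retention
probability, an empirical k/n fraction by construction.

The filtered weighted adjacency keeps the signed full-data Spearman
correlation of every edge whose probability is at least 0.90 (boundary
included) and zeroes the rest; absolute values are taken only in the
connectivity statistic. The resampling internals (1000 iterations, 75%
subsample, 30% keep rate) follow the published defaults of the
algorithm; all are exposed in configuration. A display threshold
(|r| ≥ 0.6 by default) applies only to figure/GraphML export, never to
the analysis.

A consequence worth knowing: the retention probability measures
stability *within one data set*. Because consecutive subsamples share
most of their samples, the strongest spurious correlations of a given
sample are themselves stable, so on pure-noise data a few percent of
null edges can still reach probability 0.90 (measured ≈ 4–6% of null
edges at n = 300, P = 20 with the default 30% keep rate). Planted
strong blocks are recovered with probability 1.0 throughout.

## Differential connectivity

Node connectivity is χ_i = Σ_{j≠i} |a_ij| (the full-row sum with the
diagonal excluded, equivalently the sum-minus-one form on a unit
diagonal matrix), bounded by 0 ≤ χ_i ≤ P−1 for correlation weights.
Differential connectivity between group networks A and B is
Δ_i = χ_i^A − χ_i^B.

Significance is assessed by permutation: in each of k replicates
(default k = 100) every column of each group's data matrix is permuted
independently — preserving marginals, destroying all between-feature
association — and both networks are rebuilt, giving a null Δ per
feature. The P-value is

    P_i = (1 + #(|D_i| > |Δ_i|)) / k,

capped at 1, with floor 1/k, and Benjamini–Hochberg adjustment across
the P features. Ties (|D| = |Δ|) count as non-exceedances by default,
exactly as the formula is printed; a conservative mode that counts ties
as exceedances is available for degenerate sparse-network situations
(at realistic sizes the two are indistinguishable because exact ties do
not occur).

Two calibration-relevant choices:

* Permutation replicates rebuild networks with the *same* inference
  settings as the observed networks by default. The test's validity
  argument is exchangeability of the observed and permuted statistics,
  which only holds when both are computed identically. A separate
  reduced-iteration configuration for the replicates is available for
  speed, at the cost of that exactness.
* The column-permutation scheme tests the global null of *no
  association at all*, not the weaker null of *equal networks*. On
  cohorts where both groups share genuine correlation structure, the
  null distribution is not exchangeable with the observed statistic and
  mild inflation is expected (measured ≈ 6% at nominal 5% on
  shared-block cohorts); on association-free cohorts the test is
  calibrated (measured 4.5% at nominal 5% over 20 seeds).

A design consequence of the P-value floor: at k = 100 the smallest raw
P is 0.01, so under BH a set of d true positives among P features can
reach adjusted significance at 0.05 only when 0.01·P/d ≤ 0.05. Planted
benchmarks in this package therefore use P = 20 features with 4
differential nodes; with larger panels, k should be raised accordingly.

For a set of networks within one covariate category, every unordered
pair is compared and each feature's significance frequency (share of
pairs with adjusted P ≤ 0.05) is reported; features significant in
strictly more than 70% of the comparisons form the retained set.

## COVSCA and embedding

The K association matrices (filtered adjacencies with unit diagonal
restored) are modelled as nonnegative mixtures of L shared rank-1
prototypes, S_k ≈ Σ_l c_kl z_l z_l', with c_kl ≥ 0 and ‖z_l‖ = 1; the
default L = 3. Fitting is alternating least squares: given Z, the
weights of each matrix solve a nonnegative least-squares problem; given
C, each loading is replaced by the dominant eigenvector of its weighted
residual Σ_k c_kl (S_k − Σ_{m≠l} c_km z_m z_m'). Both steps are exact
partial minimisers, so the squared-Frobenius loss is monotone
non-increasing — asserted on every fit. Convergence is declared at
relative loss change below 1e−9 or 500 iterations (a warning flags
non-convergence); the first start uses the top eigenvectors of the mean
matrix, further restarts (default 10) use random unit loadings, and the
best solution is kept. Loadings are sign- and order-indeterminate, so
recovery is measured by absolute Tucker congruence under Hungarian
matching. Goodness-of-fit is 100·(1 − Σ‖S_k − Ŝ_k‖²_F / Σ‖S_k‖²_F).
The diagonal of S_k is included in the fit; fitting raw correlation
matrices instead of filtered adjacencies is a call-site option.

The K × L score matrix places each covariate-specific network as a
point; t-SNE (perplexity 15 by default, capped at (K−2)/3 for small
collections, seeded, PCA initialisation) embeds the scores in 2-D for
cluster visualisation, with covariate-category labels carried through
for colouring.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the biology or the spectroscopy. Feature concentrations are
log-normal via a Gaussian copula: a latent normal vector with
block-structured correlation (default five 4-feature blocks at ρ = 0.6,
matching strongly co-regulated lipid sub-fraction panels) is scaled and
exponentiated with per-feature baselines shared between groups. The
default cohort geometry mirrors an aging-cohort study: groups of 259
and 96 samples, 134 features, 101 covariates in five categories
(diseases, bio-humoral, drugs, risk, familiarity), about half
dichotomous, with 10% missingness injected completely at random into
the covariates only.

"Rewired" features belong to their block in group A and are detached
into the independent background in group B. Detachment is deliberate:
moving a node between equal-size, equal-strength blocks changes its
neighbours but not its connectivity, which a connectivity-based
differential test cannot see — and it also perturbs the connectivity of
the node's former partners, so the set of truly differential nodes
would exceed the declared one. Detaching a whole block keeps the ground
truth exact. Covariate effects are planted linearly on the log scale
with standardized covariates. Dichotomous covariates are thresholded
latent Gaussians with prevalences in 0.1–0.5; continuous ones are
log-normal.

What the generator does not emulate: measurement noise structure of NMR
quantification, heavy-tailed or skewed non-log-normal features,
informative missingness, covariate–covariate correlation, or realistic
lipoprotein physiology. Passing tests demonstrate the statistical
machinery under its own assumptions, not performance on real cohort
data.

The rank-1 matrix-set generator draws orthonormal loadings (QR of a
Gaussian matrix), uniform weights in [0.5, 2], and optional symmetric
Gaussian noise — the identifiable regime in which parameter recovery is
a meaningful test.

## Problem sizes and determinism

Simulation-based checks run at reduced but statistically meaningful
sizes: type-I calibration at n = 150/group, P = 30, k = 100 over 20
seeds; recovery at n = 250/group, P = 20, ρ = 0.85 over 10 seeds; PCLRC
fidelity at n = 300, P = 20 over 10 seeds with the full 1000-iteration
configuration; permutation replicates use 100 PCLRC iterations. Every
source of randomness (cohort draws, subsampling, permutations,
cross-validation folds, restarts, t-SNE) is derived from explicit seeds
via seed sequences, and two pipeline runs with the same configuration
and seed produce byte-identical CSV/JSON outputs (figures exempt). The
pipeline manifest records content hashes of every output; resuming
reuses the simulate/preprocess/extract stages from disk.

## Known limitations

* The permutation null is the global no-association null; differential
  conclusions on strongly structured data inherit its mild
  anti-conservativeness (see above).
* PCLRC retention probabilities are within-data-set stabilities; they
  are not significance probabilities across replicate cohorts.
* The lasso extraction shrinks small covariate effects to zero; a
  covariate with no extractable signal yields an all-zero signal matrix
  and an empty network, which downstream stages handle but cannot make
  informative.
* COVSCA with rank-1 prototypes cannot represent prototype matrices of
  higher internal rank; L is a modelling choice guided by the reported
  goodness-of-fit, not selected automatically.
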