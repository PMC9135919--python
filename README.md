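# covnet

Covariate-specific metabolite–lipid association-network analysis:
PCLRC network inference, differential node connectivity with
permutation testing, and COVSCA multi-network decomposition.

## What this is for

In observational metabolomics cohorts — serum NMR panels of
small-molecule metabolites together with lipoprotein fractions and
sub-fractions — the *correlation structure* among features often
carries information that mean levels do not: sex, disease status, drug
treatment and other clinical covariates re-wire which metabolites and
lipids move together. `covnet` is a toolkit for asking, feature by
feature, "does this molecule's position in the association network
differ between two groups?" and, across a whole panel of clinical
covariates, "which covariates induce similar networks?"

It is aimed at statisticians and bioinformaticians working with
samples × features concentration tables and mixed clinical covariate
tables (continuous and dichotomous, with missing values). Because such
cohort data are typically request-only, the package ships a seeded
synthetic-cohort generator with the statistical structure the analysis
assumes, so the entire pipeline is testable end to end without any
download.

## The method

1. **Preparation** — covariates with ≥ 25% missingness are dropped, the
   rest imputed with iterative random forests; continuous variables are
   log-transformed.
2. **Covariate signal extraction** — for each clinical covariate x_m
   and feature p, fit ŷ⁽ᵖ⁾ = β̂⁽ᵖ⁾x_m + Σ_j η̂_j⁽ᵖ⁾ (x_m ∘ x_j) by
   lasso-penalised regression of y⁽ᵖ⁾ on all M covariates plus the
   first-order x_m interactions, keeping only the x_m-involving terms.
   This isolates the part of each concentration associated with x_m
   while adjusting for the other M−1 covariates, giving one n × P
   signal matrix per covariate.
3. **PCLRC network inference** — on each of 1000 75%-subsamples,
   compute the Spearman matrix, convert to CLR background-corrected
   scores z_ij = √(z_i² + z_j²) with z_i = max(0, (|r_ij| − μ_i)/σ_i),
   and mark the top 30% of edges; the marking frequency is an
   edge-retention probability p_ij. The network keeps r_ij where
   p_ij ≥ 0.90 and is zero elsewhere.
4. **Differential connectivity** — node connectivity χ_i = Σ_{j≠i}|a_ij|
   and its group difference Δ_i = χ_i^A − χ_i^B, tested by permuting
   every data column independently and rebuilding both networks k = 100
   times: P_i = (1 + #(|D_i| > |Δ_i|))/k, Benjamini–Hochberg adjusted.
   Within a covariate category, features significant in more than 70%
   of pairwise network comparisons are retained.
5. **COVSCA** — the K networks are decomposed as
   S_k ≈ Σ_{l=1}^{L} c_kl z_l z_lᵀ with c_kl ≥ 0 and L = 3 rank-1
   prototypes, fitted by alternating least squares; the K × L scores
   are embedded in 2-D with t-SNE for cluster visualisation.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

A two-group synthetic cohort with five 4-feature correlated blocks
(ρ = 0.85), where one whole block is detached in group B — those four
features are genuinely differentially connected, nothing else is:

```python
import numpy as np
from covnet import (CohortSpec, generate_cohort, PclrcConfig,
                    build_network, permutation_test)

spec = CohortSpec(
    n_per_group=(250, 250), n_features=20, n_covariates=5,
    n_blocks=5, block_size=4, within_block_rho=0.85,
    rewired_nodes=(0, 1, 2, 3),   # one block detaches in group B
    missing_rate=0.0, seed=7,
)
conc, cov, truth = generate_cohort(spec)
logA, logB = np.log(conc["A"].values), np.log(conc["B"].values)

net_A = build_network(logA, PclrcConfig(n_iterations=100, seed=1))
print(f"group A: {int((net_A.adjacency != 0).sum() / 2)} edges retained at p >= 0.90")

res = permutation_test(logA, logB, PclrcConfig(n_iterations=100), k=100, seed=2)
for i in (0, 5):
    print(f"feature {res.features[i]}: chi_A={res.chi_a[i]:.2f} "
          f"chi_B={res.chi_b[i]:.2f} delta={res.delta[i]:+.2f} "
          f"adjusted P={res.adjusted_pvalues[i]:.3f}")
flagged = [f for f, p in zip(res.features, res.adjusted_pvalues) if p <= 0.05]
print("differentially connected:", flagged)
```

Output:

```
group A: 30 edges retained at p >= 0.90
feature feat_000: chi_A=2.49 chi_B=0.25 delta=+2.24 adjusted P=0.050
feature feat_005: chi_A=2.54 chi_B=2.57 delta=-0.03 adjusted P=0.810
differentially connected: ['feat_000', 'feat_001', 'feat_002', 'feat_003']
```

Group A's network recovers the five planted blocks (30 edges ≈ 5 × 6
within-block pairs). The detached feature `feat_000` loses about 2.2
units of connectivity in group B and is flagged at the adjusted-P
boundary (with k = 100 permutations and 4 true positives among 20
features, 0.01·20/4 = 0.05 is the smallest attainable adjusted value);
the unperturbed `feat_005` keeps its connectivity in both groups. The
test flags exactly the four detached features.

The same analysis scales up through the pipeline driver, which chains
simulation (or CSV input), preprocessing, per-covariate extraction,
network inference, differential connectivity and COVSCA from one YAML
config:

```bash
covnet run --config pipeline.yaml --outdir results/ --seed 7
```

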