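"""Seeded synthetic cohorts with the correlation structure the network
analysis assumes, plus ground-truth annotations.

The generator emulates a two-group observational metabolomics cohort: a
samples x features concentration table per group (metabolites plus
lipoprotein fractions) and a samples x covariates clinical table with
mixed continuous/dichotomous columns and missing entries.  Feature
concentrations follow a Gaussian copula with block-structured
correlation on the log scale (concentrations are log-normal, so the
pipeline's log transform is exercised nontrivially).  A configurable set
of "rewired" features changes block membership between the groups:
they belong to their block in group A and are detached into the
uncorrelated background in group B, so their node connectivity genuinely
differs — equal-size block swaps would leave connectivity unchanged and
be invisible to a connectivity-based differential test.  Planted
covariate effects are added linearly on the log scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CONTINUOUS, DICHOTOMOUS, CovariateTable

COVARIATE_CATEGORIES = ("diseases", "bio-humoral", "drugs", "risk", "familiarity")


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults follow the cohort geometry the pipeline targets: group sizes
    259 and 96, 134 features (20 metabolites + 114 lipid components) and
    101 clinical covariates in five categories with under-25% missingness.

    ``covariate_effects`` maps a covariate index to a ``(feature_indices,
    beta)`` pair: the standardized covariate is added with slope beta to
    the log-scale signal of the listed features.  ``rewired_nodes`` lists
    feature indices whose block membership differs between the groups.
    """

    n_per_group: tuple[int, int] = (259, 96)
    n_features: int = 134
    n_covariates: int = 101
    n_blocks: int = 5
    block_size: int = 4
    within_block_rho: float = 0.6
    rewired_nodes: tuple[int, ...] = ()
    covariate_effects: dict[int, tuple[tuple[int, ...], float]] = field(
        default_factory=dict
    )
    missing_rate: float = 0.10
    fraction_dichotomous: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        n1, n2 = self.n_per_group
        if n1 < 3 or n2 < 3:
            raise ValueError("each group needs at least 3 samples")
        if self.n_blocks * self.block_size > self.n_features:
            raise ValueError(
                f"{self.n_blocks} blocks of {self.block_size} exceed "
                f"{self.n_features} features"
            )
        if not 0.0 <= self.within_block_rho < 1.0:
            raise ValueError("within_block_rho must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 0.25:
            raise ValueError("missing_rate must be in [0, 0.25)")
        bad = [i for i in self.rewired_nodes if not 0 <= i < self.n_features]
        if bad:
            raise ValueError(f"rewired node indices out of range: {bad}")
        for m, (features, beta) in self.covariate_effects.items():
            if not 0 <= m < self.n_covariates:
                raise ValueError(f"covariate index {m} out of range")
            bad = [p for p in features if not 0 <= p < self.n_features]
            if bad:
                raise ValueError(f"effect feature indices out of range: {bad}")
            if not np.isfinite(beta):
                raise ValueError("effect sizes must be finite")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "n_per_group" in d:
            d["n_per_group"] = tuple(d["n_per_group"])
        if "rewired_nodes" in d:
            d["rewired_nodes"] = tuple(d["rewired_nodes"])
        if "covariate_effects" in d:
            d["covariate_effects"] = {
                int(m): (tuple(v[0]), float(v[1]))
                for m, v in d["covariate_effects"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroundTruth:
    """Generator-side truth for validating downstream stages."""

    block_assignment: dict[str, np.ndarray]  # group -> per-feature block id (-1 = none)
    differential_nodes: tuple[int, ...]
    covariate_effects: dict[int, tuple[tuple[int, ...], float]]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "block_assignment": {g: a.tolist() for g, a in self.block_assignment.items()},
            "differential_nodes": list(self.differential_nodes),
            "covariate_effects": {
                str(m): [list(f), b] for m, (f, b) in self.covariate_effects.items()
            },
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _block_assignment(spec: CohortSpec, group_b: bool) -> np.ndarray:
    assign = np.full(spec.n_features, -1, dtype=int)
    for b in range(spec.n_blocks):
        lo, hi = b * spec.block_size, (b + 1) * spec.block_size
        assign[lo:hi] = b
    if group_b:
        assign[list(spec.rewired_nodes)] = -1
    return assign


def _block_covariance(assign: np.ndarray, rho: float) -> np.ndarray:
    p = len(assign)
    cov = np.eye(p)
    for b in np.unique(assign[assign >= 0]):
        idx = np.where(assign == b)[0]
        for i in idx:
            for j in idx:
                if i != j:
                    cov[i, j] = rho
    return cov


def generate_cohort(
    spec: CohortSpec,
) -> tuple[dict[str, pd.DataFrame], dict[str, CovariateTable], GroundTruth]:
    """Draw a two-group cohort with block-correlated log-normal features.

    Returns per-group concentration matrices, per-group covariate tables
    (with missing entries injected completely at random) and the ground
    truth (block memberships, the planted differential node set and the
    planted covariate effects).  Fully reproducible from ``spec.seed``.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_shared, ss_a, ss_b = root.spawn(3)
    rng_shared = np.random.default_rng(ss_shared)

    # Feature-level parameters shared by both groups.
    log_mean = rng_shared.uniform(0.5, 3.0, size=spec.n_features)
    log_sd = rng_shared.uniform(0.2, 0.5, size=spec.n_features)
    # Covariate-level parameters shared by both groups.
    n_dich = int(round(spec.fraction_dichotomous * spec.n_covariates))
    cov_types = np.array(
        [DICHOTOMOUS] * n_dich + [CONTINUOUS] * (spec.n_covariates - n_dich)
    )
    rng_shared.shuffle(cov_types)
    prevalence = rng_shared.uniform(0.1, 0.5, size=spec.n_covariates)
    cov_log_mean = rng_shared.uniform(0.0, 2.0, size=spec.n_covariates)
    cov_names = [f"cov_{m:03d}" for m in range(spec.n_covariates)]
    categories = pd.Series(
        [COVARIATE_CATEGORIES[m % len(COVARIATE_CATEGORIES)] for m in range(spec.n_covariates)],
        index=cov_names,
    )
    feat_names = [f"feat_{p:03d}" for p in range(spec.n_features)]

    concentrations: dict[str, pd.DataFrame] = {}
    covariates: dict[str, CovariateTable] = {}
    block_assignments: dict[str, np.ndarray] = {}

    for group, n, ss in (("A", spec.n_per_group[0], ss_a), ("B", spec.n_per_group[1], ss_b)):
        rng = np.random.default_rng(ss)
        assign = _block_assignment(spec, group_b=(group == "B"))
        block_assignments[group] = assign
        cov = _block_covariance(assign, spec.within_block_rho)
        chol = np.linalg.cholesky(cov)
        latent = rng.standard_normal((n, spec.n_features)) @ chol.T

        # Covariates: latent Gaussians; dichotomous thresholded at the
        # prevalence quantile, continuous mapped to log-normal.
        cov_latent = rng.standard_normal((n, spec.n_covariates))
        X = np.empty_like(cov_latent)
        from scipy.stats import norm

        for m in range(spec.n_covariates):
            if cov_types[m] == DICHOTOMOUS:
                X[:, m] = (cov_latent[:, m] < norm.ppf(prevalence[m])).astype(float)
            else:
                X[:, m] = np.exp(cov_log_mean[m] + 0.5 * cov_latent[:, m])

        # Planted effects enter the log-scale feature signal linearly.
        for m, (features, beta) in spec.covariate_effects.items():
            x = X[:, m]
            sd = x.std()
            x_std = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            latent[:, list(features)] += beta * x_std[:, None]

        conc = np.exp(log_mean + log_sd * latent)
        ids = [f"{group}_{i:04d}" for i in range(n)]
        concentrations[group] = pd.DataFrame(conc, index=ids, columns=feat_names)

        Xdf = pd.DataFrame(X, index=ids, columns=cov_names)
        if spec.missing_rate > 0:
            holes = rng.random(Xdf.shape) < spec.missing_rate
            Xdf = Xdf.mask(holes)
        covariates[group] = CovariateTable(
            Xdf, pd.Series(cov_types, index=cov_names), categories.copy()
        )

    truth = GroundTruth(
        block_assignment=block_assignments,
        differential_nodes=tuple(spec.rewired_nodes),
        covariate_effects=dict(spec.covariate_effects),
        seed=spec.seed,
    )
    return concentrations, covariates, truth


def write_cohort(
    outdir: str | Path,
    concentrations: dict[str, pd.DataFrame],
    covariates: dict[str, CovariateTable],
    truth: GroundTruth,
) -> list[Path]:
    """Write the standard pipeline input files for each group."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for group, conc in concentrations.items():
        p = outdir / f"concentrations_{group}.csv"
        conc.to_csv(p, index_label="sample_id")
        written.append(p)
        q = outdir / f"covariates_{group}.csv"
        covariates[group].to_csv(q)
        written.append(q)
        written.append(q.with_name(q.stem + "_meta.csv"))
    t = outdir / "ground_truth.json"
    truth.to_json(t)
    written.append(t)
    return written


def generate_covsca_set(
    K: int,
    L: int,
    J: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Draw K symmetric JxJ matrices from a rank-1-prototype model.

    Each matrix is ``S_k = sum_l c_kl z_l z_l' + E_k`` with nonnegative
    weights ``c_kl``, orthonormal unit loadings ``z_l`` and symmetric
    Gaussian noise of scale ``noise_sd``.  Returns the matrices, the true
    K x L weight matrix C and the true J x L loading matrix Z.
    """
    if L > J:
        raise ValueError("need L <= J")
    if K < L:
        raise ValueError("need K >= L")
    rng = np.random.default_rng(seed)
    Z, _ = np.linalg.qr(rng.standard_normal((J, L)))
    C = rng.uniform(0.5, 2.0, size=(K, L))
    matrices = []
    for k in range(K):
        S = (Z * C[k]) @ Z.T
        if noise_sd > 0:
            E = rng.standard_normal((J, J)) * noise_sd
            S = S + (E + E.T) / 2.0
        matrices.append(S)
    return matrices, C, Z
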