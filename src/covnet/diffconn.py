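"""Differential node connectivity between two association networks.

The connectivity of node i in a weighted network is the sum of the
absolute weights of its incident edges, chi_i = sum_{j != i} |a_ij|;
with correlation weights it ranges from 0 (isolated) to P-1 (perfectly
correlated with every other node).  The differential connectivity of a
feature between two group-specific networks is the difference
Delta_i = chi_i^A - chi_i^B.  Its significance is assessed with a
permutation test: every column of each group's data matrix is permuted
independently (destroying all between-feature association while keeping
the marginals), both networks are rebuilt with identical inference
settings, and the permuted differential connectivities form the null
distribution D_i.  The P-value is (1 + #(|D_i| > |Delta_i|)) / k, with
Benjamini-Hochberg adjustment across features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .network import InferredNetwork, PclrcConfig, build_network


@dataclass
class ConnectivityVector:
    """Per-node connectivity chi of one network."""

    chi: np.ndarray
    features: list[str]
    source: str = ""


@dataclass
class DiffConnectivityResult:
    """Differential connectivity with its permutation null and P-values."""

    features: list[str]
    chi_a: np.ndarray
    chi_b: np.ndarray
    delta: np.ndarray
    null: np.ndarray  # P x k permuted differential connectivities
    pvalues: np.ndarray
    adjusted_pvalues: np.ndarray
    k: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "chi_a": self.chi_a,
                "chi_b": self.chi_b,
                "delta": self.delta,
                "pvalue": self.pvalues,
                "adjusted_pvalue": self.adjusted_pvalues,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def connectivity(network: InferredNetwork | np.ndarray) -> ConnectivityVector:
    """Sum of absolute incident edge weights per node (diagonal excluded)."""
    if isinstance(network, InferredNetwork):
        A = network.adjacency
        features = network.features
    else:
        A = np.asarray(network, dtype=float)
        features = [f"feat_{i:03d}" for i in range(A.shape[0])]
    W = np.abs(A).astype(float).copy()
    np.fill_diagonal(W, 0.0)
    return ConnectivityVector(chi=W.sum(axis=1), features=list(features))


def differential_connectivity(
    netA: InferredNetwork, netB: InferredNetwork
) -> np.ndarray:
    """Delta_i = chi_i^A - chi_i^B; antisymmetric under swapping A and B."""
    if list(netA.features) != list(netB.features):
        raise ValueError("networks have different feature sets or ordering")
    return connectivity(netA).chi - connectivity(netB).chi


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of P-values")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _permutation_pvalues(
    delta: np.ndarray, null: np.ndarray, k: int, tie_mode: str
) -> np.ndarray:
    """P-value per feature from its permutation null (rows of ``null``).

    ``tie_mode="strict"`` counts only strict exceedances |D| > |Delta|;
    ``"conservative"`` also counts ties |D| = |Delta| as exceedances,
    which keeps the test valid when the null has point masses (sparse
    networks put an atom at zero).  Values are capped at 1.
    """
    abs_delta = np.abs(delta)[:, None]
    abs_null = np.abs(null)
    if tie_mode == "strict":
        exceed = (abs_null > abs_delta).sum(axis=1)
    elif tie_mode == "conservative":
        exceed = (abs_null >= abs_delta).sum(axis=1)
    else:
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    return np.minimum((1.0 + exceed) / k, 1.0)


def permutation_test(
    dataA: np.ndarray | pd.DataFrame,
    dataB: np.ndarray | pd.DataFrame,
    pclrc_cfg: PclrcConfig | None = None,
    k: int = 100,
    seed: int = 0,
    perm_cfg: PclrcConfig | None = None,
    tie_mode: str = "strict",
) -> DiffConnectivityResult:
    """Permutation test for differential connectivity between two groups.

    Observed networks are built from ``dataA``/``dataB`` with
    ``pclrc_cfg``.  For each of ``k`` replicates, every column of each
    matrix is independently permuted and both networks are rebuilt with
    ``perm_cfg`` (defaults to the same settings as the observed
    networks, which is what makes observed and null statistics
    exchangeable under the no-association null).
    """
    if k < 1:
        raise ValueError("need k >= 1 permutation replicates")
    pclrc_cfg = pclrc_cfg or PclrcConfig()
    perm_cfg = perm_cfg or pclrc_cfg
    XA = np.asarray(dataA, dtype=float)
    XB = np.asarray(dataB, dtype=float)
    if XA.shape[1] != XB.shape[1]:
        raise ValueError("groups have different feature counts")
    features = (
        list(dataA.columns)
        if isinstance(dataA, pd.DataFrame)
        else [f"feat_{i:03d}" for i in range(XA.shape[1])]
    )
    if isinstance(dataB, pd.DataFrame) and list(dataB.columns) != features:
        raise ValueError("groups have different feature labels")

    root = np.random.SeedSequence(seed)
    ss_obs_a, ss_obs_b, ss_perm = root.spawn(3)
    netA = build_network(XA, replace(pclrc_cfg, seed=_seed_of(ss_obs_a)), features)
    netB = build_network(XB, replace(pclrc_cfg, seed=_seed_of(ss_obs_b)), features)
    delta = differential_connectivity(netA, netB)

    rng = np.random.default_rng(ss_perm)
    P = XA.shape[1]
    null = np.empty((P, k))
    for r in range(k):
        permA = rng.permuted(XA, axis=0)
        permB = rng.permuted(XB, axis=0)
        sa = int(rng.integers(0, 2**31 - 1))
        sb = int(rng.integers(0, 2**31 - 1))
        na = build_network(permA, replace(perm_cfg, seed=sa), features)
        nb = build_network(permB, replace(perm_cfg, seed=sb), features)
        null[:, r] = differential_connectivity(na, nb)
    if not np.all(np.isfinite(null)):
        raise ValueError("non-finite values in the permutation null")

    pvals = _permutation_pvalues(delta, null, k, tie_mode)
    return DiffConnectivityResult(
        features=features,
        chi_a=connectivity(netA).chi,
        chi_b=connectivity(netB).chi,
        delta=delta,
        null=null,
        pvalues=pvals,
        adjusted_pvalues=bh_adjust(pvals),
        k=k,
        seed=seed,
    )


def _seed_of(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def pairwise_significance_frequency(
    datasets: dict[str, np.ndarray | pd.DataFrame],
    pclrc_cfg: PclrcConfig | None = None,
    k: int = 100,
    alpha: float = 0.05,
    retain_frac: float = 0.70,
    seed: int = 0,
    perm_cfg: PclrcConfig | None = None,
) -> pd.DataFrame:
    """Share of pairwise network comparisons in which each feature is
    significantly differentially connected.

    ``datasets`` maps network names (covariates of one category) to
    their n x P signal matrices.  Every unordered pair is compared with
    :func:`permutation_test`; a feature counts as significant in a pair
    when its BH-adjusted P-value is at most ``alpha``.  Features whose
    frequency strictly exceeds ``retain_frac`` form the retained set.
    """
    names = list(datasets)
    if len(names) < 2:
        raise ValueError("need at least 2 networks for pairwise comparison")
    root = np.random.SeedSequence(seed)
    first = datasets[names[0]]
    features = (
        list(first.columns)
        if isinstance(first, pd.DataFrame)
        else [f"feat_{i:03d}" for i in range(np.asarray(first).shape[1])]
    )
    pairs = list(combinations(names, 2))
    sig_counts = np.zeros(len(features))
    for (a, b), ss in zip(pairs, root.spawn(len(pairs))):
        res = permutation_test(
            datasets[a],
            datasets[b],
            pclrc_cfg,
            k=k,
            seed=_seed_of(ss),
            perm_cfg=perm_cfg,
        )
        sig_counts += res.adjusted_pvalues <= alpha
    freq = sig_counts / len(pairs)
    return pd.DataFrame(
        {
            "feature": features,
            "n_comparisons": len(pairs),
            "frequency": freq,
            "retained": freq > retain_frac,
        }
    )
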