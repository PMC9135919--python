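"""PCLRC association-network inference.

PCLRC (Probabilistic Context Likelihood of Relatedness on Correlation)
estimates a weighted association network among metabolites and lipid
components.  On each of many subsamples of the rows it computes a
Spearman correlation matrix, converts it to CLR background-corrected
scores, and marks the top fraction of edges; the per-edge marking
frequency across subsamples is an edge-retention probability.  The final
weighted adjacency keeps the signed Spearman correlation r_ij of every
edge whose probability reaches the threshold (default 0.90) and zeroes
the rest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class PclrcConfig:
    """PCLRC resampling settings.

    ``n_iterations`` subsamples of ``subsample_fraction`` of the samples
    are drawn without replacement; on each, the ``keep_fraction`` of
    edges with the highest CLR scores are marked (ties at the cutoff are
    all included).  ``probability_threshold`` is the marking frequency an
    edge needs to be retained in the filtered network.
    """

    n_iterations: int = 1000
    subsample_fraction: float = 0.75
    keep_fraction: float = 0.30
    probability_threshold: float = 0.90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for name in ("subsample_fraction", "keep_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise ValueError("probability_threshold must be in [0, 1]")


@dataclass
class InferredNetwork:
    """Spearman matrix R, edge-probability matrix P and filtered adjacency A."""

    correlations: np.ndarray
    probabilities: np.ndarray
    adjacency: np.ndarray
    features: list[str]
    settings: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def edge_list(self, min_abs_weight: float = 0.0) -> pd.DataFrame:
        """3-column edge list (i, j, weight) of nonzero edges.

        ``min_abs_weight`` is a display threshold (e.g. ``0.6`` to keep
        only strong correlations in figures); it does not alter the
        network itself.
        """
        i, j = np.triu_indices(self.n_features, k=1)
        w = self.adjacency[i, j]
        keep = (w != 0) & (np.abs(w) >= min_abs_weight)
        return pd.DataFrame(
            {
                "source": np.asarray(self.features)[i[keep]],
                "target": np.asarray(self.features)[j[keep]],
                "weight": w[keep],
            }
        )

    def to_graphml(self, path: str | Path, min_abs_weight: float = 0.0) -> None:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.features)
        for _, row in self.edge_list(min_abs_weight).iterrows():
            g.add_edge(row["source"], row["target"], weight=float(row["weight"]))
        nx.write_graphml(g, path)

    def save_csv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        for name, mat in (
            ("correlations", self.correlations),
            ("probabilities", self.probabilities),
            ("adjacency", self.adjacency),
        ):
            pd.DataFrame(mat, index=self.features, columns=self.features).to_csv(
                f"{prefix}_{name}.csv"
            )


def spearman_matrix(data: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Spearman rank correlation matrix of the columns of ``data``.

    Ties get average ranks.  Constant columns have undefined rank
    correlation; their entries are set to 0 with a warning.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    if np.isnan(X).any():
        raise ValueError("missing entries in data matrix")
    ranks = rankdata(X, axis=0)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s); correlations set to 0",
            stacklevel=2,
        )
        ranks = ranks.copy()
        # give constant columns unit variance so corrcoef is finite, zero after
        ranks[:, constant] = np.arange(n)[:, None]
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(ranks, rowvar=False)
    R = np.clip(R, -1.0, 1.0)
    if constant.any():
        R[constant, :] = 0.0
        R[:, constant] = 0.0
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


def clr_scores(R: np.ndarray) -> np.ndarray:
    """Context-likelihood-of-relatedness scores of a similarity matrix.

    Operates on s = |R| with the diagonal excluded.  For edge (i, j) the
    one-sided z-score against node i's background is
    ``z_i = max(0, (s_ij - mu_i) / sigma_i)`` with mu_i, sigma_i the mean
    and standard deviation of row i's off-diagonal similarities; the
    symmetric score is ``sqrt(z_i^2 + z_j^2)``.  A zero-variance
    background gives z = 0.
    """
    R = np.asarray(R, dtype=float)
    if R.shape[0] != R.shape[1] or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("CLR needs a symmetric matrix")
    p = R.shape[0]
    s = np.abs(R).copy()
    np.fill_diagonal(s, np.nan)
    mu = np.nanmean(s, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sigma = np.nanstd(s, axis=1)
    np.fill_diagonal(s, 0.0)
    z = np.zeros_like(s)
    ok = sigma > 0
    z[ok, :] = (s[ok, :] - mu[ok, None]) / sigma[ok, None]
    z = np.maximum(z, 0.0)
    out = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(out, 0.0)
    return out


def _top_edge_mask(scores: np.ndarray, keep_fraction: float) -> np.ndarray:
    """Boolean upper-triangle mask of the top-scoring edges.

    The cutoff is the value of the m-th largest score with
    m = ceil(keep_fraction * n_edges); edges tied at the cutoff are all
    included.  Zero scores carry no evidence and are never marked.
    """
    p = scores.shape[0]
    iu = np.triu_indices(p, k=1)
    vals = scores[iu]
    m = int(np.ceil(keep_fraction * len(vals)))
    if m == 0:
        return np.zeros_like(scores, dtype=bool)
    cutoff = np.partition(vals, len(vals) - m)[len(vals) - m]
    marked = (vals >= cutoff) & (vals > 0)
    mask = np.zeros_like(scores, dtype=bool)
    mask[iu] = marked
    return mask | mask.T


def pclrc_probabilities(
    data: np.ndarray | pd.DataFrame, cfg: PclrcConfig | None = None
) -> np.ndarray:
    """Edge-retention probability matrix from resampled CLR networks."""
    cfg = cfg or PclrcConfig()
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    n_sub = max(int(np.floor(cfg.subsample_fraction * n)), 3)
    if n_sub < 10 and cfg.subsample_fraction < 1.0:
        warnings.warn(f"subsample size {n_sub} is very small", stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    counts = np.zeros((p, p))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for _ in range(cfg.n_iterations):
            idx = (
                rng.choice(n, size=n_sub, replace=False)
                if n_sub < n
                else np.arange(n)
            )
            R = spearman_matrix(X[idx])
            counts += _top_edge_mask(clr_scores(R), cfg.keep_fraction)
    P = counts / cfg.n_iterations
    np.fill_diagonal(P, 0.0)
    return P


def filter_network(
    R: np.ndarray, Pmat: np.ndarray, threshold: float = 0.90
) -> np.ndarray:
    """Keep r_ij where the edge probability reaches the threshold, else 0."""
    R = np.asarray(R, dtype=float)
    Pmat = np.asarray(Pmat, dtype=float)
    if R.shape != Pmat.shape:
        raise ValueError("correlation and probability matrices differ in shape")
    A = np.where(Pmat >= threshold, R, 0.0)
    np.fill_diagonal(A, 0.0)
    return A


def build_network(
    data: np.ndarray | pd.DataFrame,
    cfg: PclrcConfig | None = None,
    features: list[str] | None = None,
) -> InferredNetwork:
    """Full PCLRC inference: Spearman + resampled CLR + probability filter."""
    cfg = cfg or PclrcConfig()
    if features is None:
        features = (
            list(data.columns)
            if isinstance(data, pd.DataFrame)
            else [f"feat_{i:03d}" for i in range(np.asarray(data).shape[1])]
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        R = spearman_matrix(data)
    Pmat = pclrc_probabilities(data, cfg)
    A = filter_network(R, Pmat, cfg.probability_threshold)
    return InferredNetwork(
        correlations=R,
        probabilities=Pmat,
        adjacency=A,
        features=list(features),
        settings=asdict(cfg),
    )
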