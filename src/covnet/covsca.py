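"""COVSCA: simultaneous component analysis of a set of association matrices.

A collection of K symmetric association matrices S_1..S_K (one per
covariate-specific network) is approximated by nonnegative combinations
of L shared rank-1 prototypes:

    S_k  ~=  sum_l  c_kl  z_l z_l',      c_kl >= 0,  ||z_l|| = 1.

The K x L weight matrix C places every network as a point in an
L-dimensional space (the scores); the loadings z_l say which features
shape each prototype.  Fitting is alternating least squares: given Z the
weights are nonnegative least squares per matrix, given C each loading
is the dominant eigenvector of the weighted residual; both steps
decrease the squared Frobenius loss, so the loss trajectory is monotone.
Goodness-of-fit is the percentage of the total squared Frobenius norm
explained.  The scores are embedded in 2-D with t-SNE for cluster
visualisation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import nnls

from .network import InferredNetwork


@dataclass
class CovscaModel:
    """Fitted COVSCA decomposition."""

    loadings: np.ndarray  # J x L, unit-norm columns
    weights: np.ndarray  # K x L, nonnegative
    loss_trajectory: list[float]
    gof: float  # percent of total squared Frobenius norm explained
    gof_per_matrix: np.ndarray
    converged: bool
    seed: int
    n_restarts: int
    features: list[str] | None = None

    @property
    def n_prototypes(self) -> int:
        return self.loadings.shape[1]

    def feature_importance(self) -> np.ndarray:
        """Per-feature importance: absolute loading per prototype."""
        return np.abs(self.loadings)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "loadings": self.loadings.tolist(),
            "weights": self.weights.tolist(),
            "gof": self.gof,
            "gof_per_matrix": self.gof_per_matrix.tolist(),
            "converged": self.converged,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
            "features": self.features,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


@dataclass
class NetworkEmbedding:
    """2-D t-SNE embedding of the COVSCA scores."""

    coordinates: np.ndarray  # K x 2
    perplexity: float
    seed: int
    labels: list[str] | None = None
    categories: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coordinates, columns=["tsne_1", "tsne_2"])
        if self.labels is not None:
            df.insert(0, "network", self.labels)
        if self.categories is not None:
            df["category"] = self.categories
        return df


def association_matrices(networks: list[InferredNetwork]) -> list[np.ndarray]:
    """Filtered signed adjacencies with unit diagonal restored."""
    if not networks:
        raise ValueError("no networks given")
    features = networks[0].features
    out = []
    for net in networks:
        if list(net.features) != list(features):
            raise ValueError("networks have mismatched feature sets")
        S = net.adjacency.astype(float).copy()
        np.fill_diagonal(S, 1.0)
        out.append((S + S.T) / 2.0)
    return out


def _nnls_weights(S_list: list[np.ndarray], Z: np.ndarray) -> np.ndarray:
    """Per-matrix nonnegative least squares of vec(S_k) on vec(z_l z_l')."""
    J, L = Z.shape
    G = np.column_stack([np.outer(Z[:, l], Z[:, l]).ravel() for l in range(L)])
    C = np.empty((len(S_list), L))
    for k, S in enumerate(S_list):
        C[k], _ = nnls(G, S.ravel())
    return C


def _loss(S_list: list[np.ndarray], C: np.ndarray, Z: np.ndarray) -> float:
    total = 0.0
    for k, S in enumerate(S_list):
        model = (Z * C[k]) @ Z.T
        total += float(np.sum((S - model) ** 2))
    return total


def fit_covsca(
    S_list: list[np.ndarray],
    L: int = 3,
    tol: float = 1e-9,
    max_iter: int = 500,
    n_restarts: int = 10,
    seed: int = 0,
    features: list[str] | None = None,
) -> CovscaModel:
    """Alternating least squares fit of the rank-1-prototype model.

    The first start initialises the loadings from the top eigenvectors
    of the mean matrix; further restarts use random unit vectors.  The
    best (lowest-loss) solution is kept.  Convergence is declared when
    the relative loss change drops below ``tol``.
    """
    K = len(S_list)
    if K == 0:
        raise ValueError("empty matrix set")
    J = S_list[0].shape[0]
    if any(S.shape != (J, J) for S in S_list):
        raise ValueError("matrices differ in dimension")
    if not 1 <= L <= J:
        raise ValueError("need 1 <= L <= J")
    if K < L:
        raise ValueError("need at least as many matrices as prototypes")
    S_list = [np.asarray(S, dtype=float) for S in S_list]
    total_norm = sum(float(np.sum(S**2)) for S in S_list)
    if total_norm == 0:
        raise ValueError("all matrices are zero")

    rng = np.random.default_rng(seed)
    mean_S = sum(S_list) / K
    evals, evecs = eigh(mean_S)
    order = np.argsort(np.abs(evals))[::-1]
    Z_eig = evecs[:, order[:L]]

    best = None
    for restart in range(max(n_restarts, 1)):
        if restart == 0:
            Z = Z_eig.copy()
        else:
            Z = rng.standard_normal((J, L))
            Z /= np.linalg.norm(Z, axis=0, keepdims=True)
        C = _nnls_weights(S_list, Z)
        traj = [_loss(S_list, C, Z)]
        converged = False
        for _ in range(max_iter):
            # loadings step: dominant eigenvector of the weighted residual
            for l in range(L):
                W = np.zeros((J, J))
                for k, S in enumerate(S_list):
                    others = (Z * C[k]) @ Z.T - C[k, l] * np.outer(Z[:, l], Z[:, l])
                    W += C[k, l] * (S - others)
                if not np.any(W):
                    continue
                top_val, top_vec = eigh(W, subset_by_index=[J - 1, J - 1])
                if top_val[0] > float(Z[:, l] @ W @ Z[:, l]):
                    Z[:, l] = top_vec[:, 0]
            C = _nnls_weights(S_list, Z)
            traj.append(_loss(S_list, C, Z))
            if traj[-2] - traj[-1] <= tol * max(traj[-2], 1e-300):
                converged = True
                break
        if best is None or traj[-1] < best[0]:
            best = (traj[-1], Z.copy(), C.copy(), traj, converged)

    loss, Z, C, traj, converged = best
    if not converged:
        warnings.warn("COVSCA did not converge within max_iter", stacklevel=2)
    # normalise: unit loadings, scale absorbed into the weights
    norms = np.linalg.norm(Z, axis=0)
    ok = norms > 0
    Z[:, ok] /= norms[ok]
    C[:, ok] *= norms[ok] ** 2

    per_matrix = np.empty(K)
    for k, S in enumerate(S_list):
        model = (Z * C[k]) @ Z.T
        denom = float(np.sum(S**2))
        per_matrix[k] = 100.0 * (1.0 - np.sum((S - model) ** 2) / denom) if denom else 100.0
    gof = 100.0 * (1.0 - loss / total_norm)
    return CovscaModel(
        loadings=Z,
        weights=C,
        loss_trajectory=traj,
        gof=gof,
        gof_per_matrix=per_matrix,
        converged=converged,
        seed=seed,
        n_restarts=n_restarts,
        features=features,
    )


def covsca_scores(model: CovscaModel) -> np.ndarray:
    """K x L score matrix: each network's coordinates on the prototypes."""
    return model.weights


def embed_networks(
    scores: np.ndarray,
    perplexity: float = 15.0,
    seed: int = 0,
    labels: list[str] | None = None,
    categories: list[str] | None = None,
) -> NetworkEmbedding:
    """2-D t-SNE embedding of the network scores."""
    from sklearn.manifold import TSNE

    scores = np.asarray(scores, dtype=float)
    K = scores.shape[0]
    if K < 4:
        raise ValueError("need at least 4 networks to embed")
    if perplexity >= (K - 1) / 3:
        raise ValueError(
            f"perplexity {perplexity} too large for {K} networks; "
            f"use a value below {(K - 1) / 3:.1f}"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=1000,
    )
    coords = tsne.fit_transform(scores)
    return NetworkEmbedding(
        coordinates=np.asarray(coords, dtype=float),
        perplexity=perplexity,
        seed=seed,
        labels=labels,
        categories=categories,
    )


def tucker_congruence(Z_true: np.ndarray, Z_est: np.ndarray) -> np.ndarray:
    """Best-matching absolute Tucker congruence per component.

    Components are matched by the Hungarian algorithm on the absolute
    congruence matrix (loadings are sign- and order-indeterminate).
    """
    from scipy.optimize import linear_sum_assignment

    A = Z_true / np.linalg.norm(Z_true, axis=0, keepdims=True)
    B = Z_est / np.linalg.norm(Z_est, axis=0, keepdims=True)
    congruence = np.abs(A.T @ B)
    row, col = linear_sum_assignment(-congruence)
    return congruence[row, col]


def plot_embedding(embedding: NetworkEmbedding, path: str | Path) -> None:
    """Scatter of the embedded networks coloured by covariate category."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = embedding.to_frame()
    fig, ax = plt.subplots(figsize=(6, 5))
    if embedding.categories is not None:
        for cat, sub in df.groupby("category"):
            ax.scatter(sub["tsne_1"], sub["tsne_2"], label=str(cat), s=30)
        ax.legend(fontsize=8)
    else:
        ax.scatter(df["tsne_1"], df["tsne_2"], s=30)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_loadings(model: CovscaModel, path: str | Path) -> None:
    """Bar plots of per-feature loadings for each prototype."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    L = model.n_prototypes
    J = model.loadings.shape[0]
    names = model.features or [f"feat_{i:03d}" for i in range(J)]
    fig, axes = plt.subplots(L, 1, figsize=(max(6, J * 0.12), 2.2 * L), squeeze=False)
    for l in range(L):
        ax = axes[l, 0]
        ax.bar(range(J), model.loadings[:, l])
        ax.set_ylabel(f"z_{l + 1}")
        ax.set_xticks([])
    axes[-1, 0].set_xticks(range(J))
    axes[-1, 0].set_xticklabels(names, rotation=90, fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
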