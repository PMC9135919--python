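"""Extraction of the covariate-associated part of each feature.

For a chosen clinical covariate x_m, every feature's concentration
vector y^(p) is regressed on all M standardized covariates plus the
first-order interactions of x_m with the others; the extracted signal
keeps only the terms involving x_m:

    yhat^(p) = b_m x_m + sum_{j != m} e_j (x_m o x_j),

which isolates the part of y^(p) associated with x_m while implicitly
adjusting for the remaining M-1 covariates.  With ~2M-1 design columns
the fit is near- or under-determined at cohort sample sizes, so the
coefficients are estimated by lasso-penalized least squares with the
penalty chosen by cross-validation; an unpenalized mode is available for
small, well-posed problems.  Repeating the extraction for every
covariate yields one n x P signal matrix per covariate, the input to
the covariate-specific network inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .preprocess import CovariateTable


@dataclass
class ExtractConfig:
    """Penalty settings for the per-feature regressions."""

    penalty: str = "lasso"  # "lasso" or "none"
    cv_folds: int = 10
    n_alphas: int = 50
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.penalty not in ("lasso", "none"):
            raise ValueError("penalty must be 'lasso' or 'none'")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class RegressionDesign:
    """Design matrix for one target covariate.

    Columns: the standardized target covariate followed by its
    elementwise products with every other standardized covariate
    (constant columns dropped).  ``target_columns`` marks the columns
    whose fitted contribution forms the extracted signal — here all of
    them; the full fitting design additionally contains the other
    covariates' main effects (see :func:`extract_signal`).
    """

    covariate_id: str
    matrix: np.ndarray
    column_names: list[str]
    standardization: pd.DataFrame  # per-covariate mean and sd

    @property
    def width(self) -> int:
        return self.matrix.shape[1]


def _standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Z = (X - mu) / sd.replace(0.0, 1.0)
    return Z, pd.DataFrame({"mean": mu, "sd": sd})


def _as_frame(X: CovariateTable | pd.DataFrame) -> pd.DataFrame:
    X = X.data if isinstance(X, CovariateTable) else X
    if X.isna().values.any():
        raise ValueError("covariate table has missing values; impute first")
    return X


def build_design(
    X: CovariateTable | pd.DataFrame, m: str
) -> RegressionDesign:
    """Design of the x_m-involving terms: [x_m, x_m o x_j for j != m]."""
    Xdf = _as_frame(X)
    if m not in Xdf.columns:
        raise KeyError(f"covariate {m!r} not in table")
    Z, stats = _standardize(Xdf)
    cols = [np.asarray(Z[m])]
    names = [str(m)]
    dropped = []
    for j in Xdf.columns:
        if j == m:
            continue
        prod = np.asarray(Z[m]) * np.asarray(Z[j])
        if np.ptp(prod) == 0:
            dropped.append(str(j))
            continue
        cols.append(prod)
        names.append(f"{m}:{j}")
    if np.ptp(cols[0]) == 0:
        raise ValueError(f"target covariate {m!r} is constant")
    if dropped:
        warnings.warn(
            f"dropped constant interaction column(s) for {dropped}", stacklevel=2
        )
    return RegressionDesign(
        covariate_id=str(m),
        matrix=np.column_stack(cols),
        column_names=names,
        standardization=stats,
    )


@dataclass
class CovariateSignalMatrix:
    """Extracted n x P signal for one covariate, with fit diagnostics."""

    covariate_id: str
    values: pd.DataFrame  # n x P extracted signal
    coefficients: pd.DataFrame  # features x design columns (x_m terms only)
    r_squared: pd.Series  # full-model R^2 per feature
    settings: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="sample_id")


def extract_signal(
    Y: pd.DataFrame,
    X: CovariateTable | pd.DataFrame,
    m: str,
    cfg: ExtractConfig | None = None,
    seed: int = 0,
) -> CovariateSignalMatrix:
    """Extract the x_m-associated signal of every feature.

    Each feature is regressed on the full design (all standardized main
    effects plus the x_m interactions); the returned signal is the
    fitted contribution of the x_m-involving columns only.
    """
    cfg = cfg or ExtractConfig()
    Xdf = _as_frame(X)
    if not Y.index.equals(Xdf.index):
        raise ValueError("feature matrix and covariate table are not row-aligned")
    design = build_design(X, m)
    Z, _ = _standardize(Xdf)
    other_mains = [j for j in Xdf.columns if j != m]
    full = np.column_stack([design.matrix, np.asarray(Z[other_mains])])
    n, w = full.shape
    target_idx = np.arange(design.width)

    coefs = np.zeros((Y.shape[1], design.width))
    signal = np.zeros((n, Y.shape[1]))
    r2 = np.zeros(Y.shape[1])
    rng = np.random.default_rng(seed)
    for p, feat in enumerate(Y.columns):
        y = np.asarray(Y[feat], dtype=float)
        if cfg.penalty == "none":
            Xc = np.column_stack([np.ones(n), full])
            beta, _, rank, _ = np.linalg.lstsq(Xc, y, rcond=None)
            if rank < Xc.shape[1]:
                raise np.linalg.LinAlgError(
                    "rank-deficient unpenalized fit; use penalty='lasso'"
                )
            fitted = Xc @ beta
            b = beta[1:]
        else:
            cv = KFold(cfg.cv_folds, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
            model = LassoCV(
                alphas=cfg.n_alphas,
                cv=cv,
                max_iter=cfg.max_iter,
                random_state=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(full, y)
            fitted = model.predict(full)
            b = model.coef_
        coefs[p] = b[target_idx]
        signal[:, p] = design.matrix @ b[target_idx]
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2[p] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    return CovariateSignalMatrix(
        covariate_id=str(m),
        values=pd.DataFrame(signal, index=Y.index, columns=Y.columns),
        coefficients=pd.DataFrame(
            coefs, index=Y.columns, columns=design.column_names
        ),
        r_squared=pd.Series(r2, index=Y.columns),
        settings={"penalty": cfg.penalty, "cv_folds": cfg.cv_folds, "seed": seed},
    )


def extract_all(
    Y: pd.DataFrame,
    X: CovariateTable | pd.DataFrame,
    cfg: ExtractConfig | None = None,
    seed: int = 0,
    covariates: list[str] | None = None,
) -> dict[str, CovariateSignalMatrix]:
    """One extracted signal matrix per covariate (results independent
    across covariates, so the loop is trivially parallelizable)."""
    Xdf = _as_frame(X)
    targets = list(covariates) if covariates is not None else list(Xdf.columns)
    root = np.random.SeedSequence(seed)
    out = {}
    for m, ss in zip(targets, root.spawn(len(targets))):
        child = int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        out[str(m)] = extract_signal(Y, X, m, cfg, seed=child)
    return out
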