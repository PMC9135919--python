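"""Data preparation: covariate missingness filter, forest-based imputation,
log transformation and sample exclusion.

The rules mirror common practice for NMR metabolomics cohort tables:
clinical covariates with 25% or more missing entries are dropped, the
remainder are imputed with an iterative random-forest scheme (each
incomplete column is regressed/classified on all others and the loop
repeats until the imputed values stabilise), and continuous variables are
natural-log transformed.  Dichotomous (0/1) covariates pass through the
log transform unchanged, since log(0) is undefined and a monotone
transform of a binary indicator carries no information anyway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

CONTINUOUS = "continuous"
DICHOTOMOUS = "dichotomous"


@dataclass
class CovariateTable:
    """Samples x covariates clinical table with per-column type metadata.

    Parameters
    ----------
    data:
        Samples x covariates values; missing entries are NaN.
    types:
        Per-column variable type, ``"continuous"`` or ``"dichotomous"``.
    categories:
        Optional per-column category label (e.g. diseases, bio-humoral,
        drugs, risk, familiarity) used to group covariate-specific
        networks downstream.
    """

    data: pd.DataFrame
    types: pd.Series
    categories: pd.Series | None = None

    def __post_init__(self) -> None:
        self.types = pd.Series(self.types).reindex(self.data.columns)
        if self.types.isna().any():
            missing = list(self.types.index[self.types.isna()])
            raise ValueError(f"missing type declaration for columns: {missing}")
        bad = sorted(set(self.types) - {CONTINUOUS, DICHOTOMOUS})
        if bad:
            raise ValueError(f"unknown covariate types: {bad}")
        if self.categories is not None:
            self.categories = pd.Series(self.categories).reindex(self.data.columns)

    @property
    def columns(self) -> pd.Index:
        return self.data.columns

    def copy(self) -> "CovariateTable":
        return CovariateTable(
            self.data.copy(),
            self.types.copy(),
            None if self.categories is None else self.categories.copy(),
        )

    def select(self, columns) -> "CovariateTable":
        return CovariateTable(
            self.data[columns],
            self.types[columns],
            None if self.categories is None else self.categories[columns],
        )

    def missing_fraction(self) -> pd.Series:
        return self.data.isna().mean(axis=0)

    # --- I/O -----------------------------------------------------------
    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        path = Path(path)
        self.data.to_csv(path, index_label="sample_id")
        if meta_path is None:
            meta_path = path.with_name(path.stem + "_meta.csv")
        meta = pd.DataFrame({"covariate": self.data.columns, "type": self.types.values})
        if self.categories is not None:
            meta["category"] = self.categories.values
        meta.to_csv(meta_path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, meta_path: str | Path | None = None
    ) -> "CovariateTable":
        path = Path(path)
        data = pd.read_csv(path, index_col=0)
        if meta_path is None:
            candidate = path.with_name(path.stem + "_meta.csv")
            meta_path = candidate if candidate.exists() else None
        if meta_path is not None:
            meta = pd.read_csv(meta_path)
            types = pd.Series(meta["type"].values, index=meta["covariate"])
            categories = (
                pd.Series(meta["category"].values, index=meta["covariate"])
                if "category" in meta
                else None
            )
        else:
            types = pd.Series(
                {
                    c: DICHOTOMOUS
                    if set(data[c].dropna().unique()) <= {0, 1}
                    else CONTINUOUS
                    for c in data.columns
                }
            )
            categories = None
        return cls(data, types, categories)


@dataclass
class PreprocessConfig:
    """Settings for the preparation stage.

    ``max_missing_fraction`` is the strict upper bound on per-covariate
    missingness (columns at or above it are dropped).  ``log_offset`` is
    added before taking logs to accommodate exact zeros.  The imputer
    settings control the iterative random-forest loop.
    """

    max_missing_fraction: float = 0.25
    log_offset: float = 0.0
    n_trees: int = 100
    max_imputer_iterations: int = 10
    excluded_sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in (0, 1]")
        if self.log_offset < 0:
            raise ValueError("log_offset must be nonnegative")


def exclude_samples(
    data: pd.DataFrame | CovariateTable, cfg: PreprocessConfig
) -> pd.DataFrame | CovariateTable:
    """Drop flagged sample rows (explicit ID list in the config)."""
    if isinstance(data, CovariateTable):
        keep = ~data.data.index.isin(cfg.excluded_sample_ids)
        return CovariateTable(data.data.loc[keep], data.types, data.categories)
    keep = ~data.index.isin(cfg.excluded_sample_ids)
    return data.loc[keep]


def filter_missing_covariates(
    covariates: CovariateTable, cfg: PreprocessConfig | None = None
) -> tuple[CovariateTable, dict]:
    """Retain covariates whose missing fraction is strictly below the cap.

    Returns the filtered table and a report listing the dropped columns
    with their missing fractions.  Raises if no column survives.
    """
    cfg = cfg or PreprocessConfig()
    frac = covariates.missing_fraction()
    keep = frac.index[frac < cfg.max_missing_fraction]
    dropped = frac.index.difference(keep, sort=False)
    if len(keep) == 0:
        raise ValueError(
            "all covariates exceed the missingness threshold "
            f"({cfg.max_missing_fraction:.0%}); nothing left to analyse"
        )
    report = {
        "max_missing_fraction": cfg.max_missing_fraction,
        "n_retained": int(len(keep)),
        "dropped": {c: float(frac[c]) for c in dropped},
    }
    return covariates.select(list(keep)), report


def _initial_fill(data: pd.DataFrame, types: pd.Series) -> pd.DataFrame:
    filled = data.copy()
    for c in data.columns:
        col = data[c]
        if not col.isna().any():
            continue
        if types[c] == DICHOTOMOUS:
            mode = col.mode(dropna=True)
            fill = float(mode.iloc[0]) if len(mode) else 0.0
        else:
            fill = float(col.mean(skipna=True))
        filled[c] = col.fillna(fill)
    return filled


def impute_covariates(
    covariates: CovariateTable,
    cfg: PreprocessConfig | None = None,
    seed: int = 0,
) -> tuple[CovariateTable, dict]:
    """Iterative random-forest imputation of missing covariate values.

    Each incomplete column is modelled on all other columns with a random
    forest (regressor for continuous, classifier for dichotomous) trained
    on its observed rows; missing entries are replaced by the forest's
    predictions.  Columns are visited in order of increasing missingness
    and the sweep repeats until the total change in the imputed values
    stops decreasing, or a maximum number of iterations is reached.
    Observed entries are never modified.
    """
    cfg = cfg or PreprocessConfig()
    data = covariates.data
    if not np.issubdtype(np.asarray(data.values).dtype, np.number):
        raise ValueError("covariate table contains non-numeric cells")
    mask = data.isna()
    if not mask.values.any():
        return covariates.copy(), {"n_iterations": 0, "imputed_cells": 0}

    rng = np.random.default_rng(seed)
    filled = _initial_fill(data, covariates.types)
    order = list(mask.sum(axis=0).sort_values(kind="stable").index)
    order = [c for c in order if mask[c].any()]

    prev_change = np.inf
    best = filled.copy()
    n_iter = 0
    for n_iter in range(1, cfg.max_imputer_iterations + 1):
        previous = filled.copy()
        for c in order:
            obs = ~mask[c].values
            others = [x for x in filled.columns if x != c]
            X_obs = filled.loc[obs, others].values
            X_mis = filled.loc[~obs, others].values
            y_obs = filled.loc[obs, c].values
            col_seed = int(rng.integers(0, 2**31 - 1))
            if covariates.types[c] == DICHOTOMOUS:
                if len(np.unique(y_obs)) < 2:
                    pred = np.full(X_mis.shape[0], y_obs[0])
                else:
                    model = RandomForestClassifier(
                        n_estimators=cfg.n_trees, random_state=col_seed
                    )
                    model.fit(X_obs, y_obs.astype(int))
                    pred = model.predict(X_mis).astype(float)
            else:
                model = RandomForestRegressor(
                    n_estimators=cfg.n_trees, random_state=col_seed
                )
                model.fit(X_obs, y_obs)
                pred = model.predict(X_mis)
            filled.loc[~obs, c] = pred
        num = ((filled - previous) ** 2).values.sum()
        den = (filled**2).values.sum()
        change = num / den if den > 0 else 0.0
        if change >= prev_change:
            filled = previous  # revert: stopping rule hit after divergence
            break
        prev_change = change
        best = filled.copy()
    else:
        filled = best

    out = covariates.copy()
    out.data = filled
    report = {"n_iterations": n_iter, "imputed_cells": int(mask.values.sum())}
    return out, report


def log_transform(
    data: pd.DataFrame | CovariateTable, cfg: PreprocessConfig | None = None
):
    """Natural-log transform continuous columns; pass 0/1 columns through.

    A concentration matrix (plain DataFrame) is treated as all-continuous.
    Raises a ValueError naming the offending column if any value plus the
    offset is not strictly positive.
    """
    cfg = cfg or PreprocessConfig()
    if isinstance(data, CovariateTable):
        out = data.copy()
        for c in out.columns:
            if out.types[c] == DICHOTOMOUS:
                continue
            out.data[c] = _log_column(out.data[c], c, cfg.log_offset)
        return out
    out = data.copy()
    for c in out.columns:
        out[c] = _log_column(out[c], c, cfg.log_offset)
    return out


def _log_column(col: pd.Series, name: str, offset: float) -> pd.Series:
    shifted = col + offset
    bad = shifted[shifted.notna() & (shifted <= 0)]
    if len(bad):
        raise ValueError(
            f"column {name!r} has {len(bad)} nonpositive value(s) after "
            f"offset {offset}; log transform undefined"
        )
    return np.log(shifted)


def preprocess_report_to_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
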