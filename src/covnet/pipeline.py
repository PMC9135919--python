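"""End-to-end orchestration: simulate -> preprocess -> extract -> infer
-> compare -> decompose -> embed.

The pipeline is driven by a YAML/dict config with one block per stage;
every stage seed is derived deterministically from the global seed, so a
rerun with the same config produces byte-identical CSV/JSON outputs
(figures exempt).  A JSON manifest records per-stage outputs with
content hashes for provenance.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import covsca as covsca_mod
from . import diffconn as diffconn_mod
from .extract import ExtractConfig, extract_all
from .network import PclrcConfig, build_network
from .preprocess import (
    CovariateTable,
    PreprocessConfig,
    exclude_samples,
    filter_missing_covariates,
    impute_covariates,
    log_transform,
)
from .synthetic import CohortSpec, generate_cohort, write_cohort

log = logging.getLogger("covnet")

STAGES = ("simulate", "preprocess", "extract", "infer", "diffnet", "covsca", "embed")

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "covnet_run",
    "group_names": ["A", "B"],
    "simulation": None,  # CohortSpec fields; exclusive with `inputs`
    "inputs": None,  # {"concentrations": {grp: path}, "covariates": {grp: path}}
    "preprocess": {
        "max_missing_fraction": 0.25,
        "log_offset": 0.0,
        "n_trees": 100,
        "max_imputer_iterations": 10,
        "excluded_sample_ids": [],
    },
    "extract": {"penalty": "lasso", "cv_folds": 10, "covariates": None},
    "network": {
        "n_iterations": 1000,
        "subsample_fraction": 0.75,
        "keep_fraction": 0.30,
        "probability_threshold": 0.90,
        "display_threshold": 0.6,
    },
    "diffconn": {
        "k": 100,
        "alpha": 0.05,
        "retain_frac": 0.70,
        "perm_iterations": 100,
        "tie_mode": "strict",
    },
    "covsca": {"L": 3, "n_restarts": 10, "max_iter": 500, "tol": 1e-9},
    "embed": {"perplexity": 15.0},
    "plots": False,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline settings (defaults merged with user overrides)."""

    settings: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __post_init__(self) -> None:
        s = self.settings
        if (s.get("simulation") is None) == (s.get("inputs") is None):
            raise ValueError(
                "config must provide exactly one of 'simulation' or 'inputs'"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(_deep_merge(DEFAULTS, d))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text()) or {}
        d.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(d)

    def __getitem__(self, key):
        return self.settings[key]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(conc_path: str | Path, cov_path: str | Path) -> dict:
    """Check sample alignment, numeric parsing, type declarations and
    duplicate IDs of a concentration/covariate file pair."""
    violations: list[str] = []
    conc = pd.read_csv(conc_path, index_col=0)
    cov_table = CovariateTable.from_csv(cov_path)
    cov = cov_table.data
    for name, df in (("concentrations", conc), ("covariates", cov)):
        dup = df.index[df.index.duplicated()].unique()
        if len(dup):
            violations.append(f"{name}: duplicate sample IDs {list(dup)}")
    missing_in_cov = conc.index.difference(cov.index)
    missing_in_conc = cov.index.difference(conc.index)
    if len(missing_in_cov):
        violations.append(
            f"alignment: {len(missing_in_cov)} sample(s) absent from covariates: "
            f"{list(missing_in_cov[:5])}"
        )
    if len(missing_in_conc):
        violations.append(
            f"alignment: {len(missing_in_conc)} sample(s) absent from concentrations: "
            f"{list(missing_in_conc[:5])}"
        )
    for c in conc.columns:
        if not pd.api.types.is_numeric_dtype(conc[c]):
            violations.append(f"concentrations: column {c!r} is not numeric")
    for c in cov.columns:
        if not pd.api.types.is_numeric_dtype(cov[c]):
            violations.append(f"covariates: column {c!r} is not numeric")
        elif cov_table.types[c] == "dichotomous":
            values = set(cov[c].dropna().unique())
            if not values <= {0, 1}:
                violations.append(
                    f"covariates: dichotomous column {c!r} has values {sorted(values - {0, 1})}"
                )
    return {"violations": violations, "n_samples": int(len(conc)), "valid": not violations}


def _stage_seed(root: np.random.SeedSequence, index: int) -> int:
    return int(root.spawn(index + 1)[index].generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def run_pipeline(config: PipelineConfig | dict, resume: bool = False) -> dict:
    """Execute all stages in order and return the run manifest."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    s = config.settings
    outdir = Path(s["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(int(s["seed"]))
    groups = list(s["group_names"])
    # outdir excluded so manifests from runs into different directories compare equal
    manifest: dict = {
        "config": {k: v for k, v in s.items() if k != "outdir"},
        "stages": [],
    }

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": [
                    {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
                    for p in sorted(outputs)
                ],
            }
        )

    t0 = time.time()

    # ------------------------------------------------------------------ simulate
    sim_dir = outdir / "simulated"
    if s["simulation"] is not None:
        sim_files = [sim_dir / f"concentrations_{g}.csv" for g in groups] + [
            sim_dir / f"covariates_{g}.csv" for g in groups
        ]
        if resume and all(p.exists() for p in sim_files):
            conc = {
                g: pd.read_csv(sim_dir / f"concentrations_{g}.csv", index_col=0)
                for g in groups
            }
            cov = {
                g: CovariateTable.from_csv(sim_dir / f"covariates_{g}.csv")
                for g in groups
            }
            record("simulate", sim_files)
            log.info("simulate: resumed from %s", sim_dir)
        else:
            spec_fields = dict(s["simulation"])
            spec_fields.setdefault("seed", _stage_seed(root, 0))
            spec = CohortSpec.from_dict(spec_fields)
            conc, cov, truth = generate_cohort(spec)
            conc = {g: conc[k] for g, k in zip(groups, conc)}
            cov = {g: cov[k] for g, k in zip(groups, cov)}
            written = write_cohort(sim_dir, conc, cov, truth)
            record("simulate", written)
            log.info("simulate: %d groups, %.1fs", len(groups), time.time() - t0)
    else:
        paths = s["inputs"]
        conc = {
            g: pd.read_csv(paths["concentrations"][g], index_col=0) for g in groups
        }
        cov = {g: CovariateTable.from_csv(paths["covariates"][g]) for g in groups}
        record("simulate", [])

    # ---------------------------------------------------------------- preprocess
    pp = s["preprocess"]
    pp_cfg = PreprocessConfig(
        max_missing_fraction=pp["max_missing_fraction"],
        log_offset=pp["log_offset"],
        n_trees=pp["n_trees"],
        max_imputer_iterations=pp["max_imputer_iterations"],
        excluded_sample_ids=list(pp["excluded_sample_ids"]),
    )
    pre_dir = outdir / "preprocessed"
    pre_dir.mkdir(exist_ok=True)
    pp_seed = _stage_seed(root, 1)
    outputs = []
    report: dict = {}
    log_conc: dict[str, pd.DataFrame] = {}
    log_cov: dict[str, CovariateTable] = {}
    pre_files = [pre_dir / f"concentrations_{g}.csv" for g in groups] + [
        pre_dir / f"covariates_{g}.csv" for g in groups
    ]
    if resume and all(p.exists() for p in pre_files):
        for g in groups:
            log_conc[g] = pd.read_csv(pre_dir / f"concentrations_{g}.csv", index_col=0)
            log_cov[g] = CovariateTable.from_csv(pre_dir / f"covariates_{g}.csv")
        record("preprocess", pre_files + [pre_dir / "preprocess_report.json"])
        log.info("preprocess: resumed from %s", pre_dir)
        _resumed_preprocess = True
    else:
        _resumed_preprocess = False
    for i, g in enumerate(groups if not _resumed_preprocess else []):
        c = exclude_samples(conc[g], pp_cfg)
        x = exclude_samples(cov[g], pp_cfg)
        x, filt_report = filter_missing_covariates(x, pp_cfg)
        x, imp_report = impute_covariates(x, pp_cfg, seed=pp_seed + i)
        log_conc[g] = log_transform(c, pp_cfg)
        log_cov[g] = log_transform(x, pp_cfg)
        report[g] = {"filter": filt_report, "impute": imp_report}
        p1 = pre_dir / f"concentrations_{g}.csv"
        log_conc[g].to_csv(p1, index_label="sample_id")
        p2 = pre_dir / f"covariates_{g}.csv"
        log_cov[g].to_csv(p2)
        outputs += [p1, p2, p2.with_name(p2.stem + "_meta.csv")]
    if not _resumed_preprocess:
        rep_path = pre_dir / "preprocess_report.json"
        rep_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        outputs.append(rep_path)
        record("preprocess", outputs)
        log.info("preprocess: done, %.1fs", time.time() - t0)

    # ------------------------------------------------------------------- extract
    ex = s["extract"]
    ex_cfg = ExtractConfig(penalty=ex["penalty"], cv_folds=ex["cv_folds"])
    targets = ex["covariates"]
    ex_dir = outdir / "signals"
    ex_dir.mkdir(exist_ok=True)
    ex_seed = _stage_seed(root, 2)
    signals: dict[str, dict] = {}
    outputs = []
    expected = {
        g: [str(m) for m in (targets or list(log_cov[g].columns))] for g in groups
    }
    sig_files = [
        ex_dir / f"signal_{g}_{m}.csv" for g in groups for m in expected[g]
    ]
    if resume and sig_files and all(p.exists() for p in sig_files):
        from .extract import CovariateSignalMatrix

        for g in groups:
            signals[g] = {}
            for m in expected[g]:
                values = pd.read_csv(ex_dir / f"signal_{g}_{m}.csv", index_col=0)
                coefs = pd.read_csv(ex_dir / f"coefficients_{g}_{m}.csv", index_col=0)
                signals[g][m] = CovariateSignalMatrix(
                    covariate_id=m,
                    values=values,
                    coefficients=coefs,
                    r_squared=pd.Series(np.nan, index=values.columns),
                )
        record("extract", sig_files)
        log.info("extract: resumed from %s", ex_dir)
    else:
        for i, g in enumerate(groups):
            signals[g] = extract_all(
                log_conc[g], log_cov[g], ex_cfg, seed=ex_seed + i, covariates=targets
            )
            for m, sig in signals[g].items():
                p = ex_dir / f"signal_{g}_{m}.csv"
                sig.to_csv(p)
                outputs.append(p)
                q = ex_dir / f"coefficients_{g}_{m}.csv"
                sig.coefficients.to_csv(q, index_label="feature")
                outputs.append(q)
        record("extract", outputs)
    log.info("extract: %d covariates x %d groups, %.1fs",
             len(next(iter(signals.values()))), len(groups), time.time() - t0)

    # --------------------------------------------------------------------- infer
    nw = s["network"]
    net_cfg = PclrcConfig(
        n_iterations=nw["n_iterations"],
        subsample_fraction=nw["subsample_fraction"],
        keep_fraction=nw["keep_fraction"],
        probability_threshold=nw["probability_threshold"],
    )
    net_dir = outdir / "networks"
    net_dir.mkdir(exist_ok=True)
    net_seed = _stage_seed(root, 3)
    networks: dict[str, dict] = {g: {} for g in groups}
    overall: dict[str, object] = {}
    outputs = []
    counter = 0
    from dataclasses import replace as _replace

    for g in groups:
        overall[g] = build_network(
            log_conc[g], _replace(net_cfg, seed=net_seed + counter)
        )
        counter += 1
        p = net_dir / f"edges_overall_{g}.csv"
        overall[g].edge_list().to_csv(p, index=False)
        overall[g].to_graphml(
            net_dir / f"network_overall_{g}.graphml", nw["display_threshold"]
        )
        outputs.append(p)
        for m, sig in signals[g].items():
            net = build_network(sig.values, _replace(net_cfg, seed=net_seed + counter))
            counter += 1
            networks[g][m] = net
            p = net_dir / f"edges_{g}_{m}.csv"
            net.edge_list().to_csv(p, index=False)
            outputs.append(p)
            q = net_dir / f"probabilities_{g}_{m}.csv"
            pd.DataFrame(net.probabilities, index=net.features, columns=net.features).to_csv(q)
            outputs.append(q)
    record("infer", outputs)
    log.info("infer: %d networks, %.1fs", counter, time.time() - t0)

    # -------------------------------------------------------------------- diffnet
    dc = s["diffconn"]
    perm_cfg = _replace(net_cfg, n_iterations=int(dc["perm_iterations"]))
    dc_dir = outdir / "diffconn"
    dc_dir.mkdir(exist_ok=True)
    dc_seed = _stage_seed(root, 4)
    outputs = []
    res = diffconn_mod.permutation_test(
        log_conc[groups[0]],
        log_conc[groups[1]],
        net_cfg,
        k=int(dc["k"]),
        seed=dc_seed,
        perm_cfg=perm_cfg,
        tie_mode=dc["tie_mode"],
    )
    p = dc_dir / f"diffconn_overall_{groups[0]}_vs_{groups[1]}.csv"
    res.to_csv(p)
    outputs.append(p)
    for i, m in enumerate(sorted(signals[groups[0]])):
        res_m = diffconn_mod.permutation_test(
            signals[groups[0]][m].values,
            signals[groups[1]][m].values,
            net_cfg,
            k=int(dc["k"]),
            seed=dc_seed + 1 + i,
            perm_cfg=perm_cfg,
            tie_mode=dc["tie_mode"],
        )
        p = dc_dir / f"diffconn_{m}_{groups[0]}_vs_{groups[1]}.csv"
        res_m.to_csv(p)
        outputs.append(p)
    record("diffnet", outputs)
    log.info("diffnet: done, %.1fs", time.time() - t0)

    # --------------------------------------------------------------------- covsca
    cv = s["covsca"]
    cov_dir = outdir / "covsca"
    cov_dir.mkdir(exist_ok=True)
    cv_seed = _stage_seed(root, 5)
    outputs = []
    scores_frames = []
    for g in groups:
        order = sorted(networks[g])
        nets = [networks[g][m] for m in order]
        S_list = covsca_mod.association_matrices(nets)
        model = covsca_mod.fit_covsca(
            S_list,
            L=int(cv["L"]),
            tol=float(cv["tol"]),
            max_iter=int(cv["max_iter"]),
            n_restarts=int(cv["n_restarts"]),
            seed=cv_seed,
            features=nets[0].features,
        )
        model.to_json(cov_dir / f"covsca_{g}.json")
        outputs.append(cov_dir / f"covsca_{g}.json")
        sc = pd.DataFrame(
            covsca_mod.covsca_scores(model),
            index=order,
            columns=[f"component_{l + 1}" for l in range(model.n_prototypes)],
        )
        sc.insert(0, "group", g)
        p = cov_dir / f"scores_{g}.csv"
        sc.to_csv(p, index_label="covariate")
        outputs.append(p)
        scores_frames.append(sc)
        if s["plots"]:
            covsca_mod.plot_loadings(model, cov_dir / f"loadings_{g}.png")
    record("covsca", outputs)
    log.info("covsca: done, %.1fs", time.time() - t0)

    # ---------------------------------------------------------------------- embed
    em = s["embed"]
    em_dir = outdir / "embedding"
    em_dir.mkdir(exist_ok=True)
    em_seed = _stage_seed(root, 6)
    all_scores = pd.concat(scores_frames)
    K = len(all_scores)
    perplexity = min(float(em["perplexity"]), max((K - 2) / 3.0, 1.0))
    categories = None
    cov0 = log_cov[groups[0]]
    if cov0.categories is not None:
        categories = [
            str(cov0.categories.get(m, "unknown")) for m in all_scores.index
        ]
    embedding = covsca_mod.embed_networks(
        all_scores.drop(columns="group").values,
        perplexity=perplexity,
        seed=em_seed,
        labels=[f"{g}:{m}" for g, m in zip(all_scores["group"], all_scores.index)],
        categories=categories,
    )
    p = em_dir / "embedding.csv"
    embedding.to_frame().to_csv(p, index=False)
    outputs = [p]
    if s["plots"]:
        covsca_mod.plot_embedding(embedding, em_dir / "embedding.png")
    record("embed", outputs)
    log.info("embed: done, %.1fs", time.time() - t0)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("pipeline complete: %d stages, %.1fs", len(manifest["stages"]), time.time() - t0)
    return manifest
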