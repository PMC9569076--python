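"""End-to-end orchestration: discovery and validation workflows.

``run_discovery`` executes preprocess -> screen -> select -> model ->
network -> MR -> mediation on one cohort directory and writes every stage
output plus a manifest (input hashes, per-stage seeds, package version).
``run_validation`` applies the frozen discovery coefficients to an
independent cohort and reports quartile stratification, the log-rank test,
and a replication screen at P < 0.05.

The master seed deterministically derives per-stage seeds through
``numpy.random.SeedSequence(master_seed, spawn_key=(stage_index,))`` so each
stage is independently reproducible and a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mediation as med_mod
from . import model as model_mod
from . import mr as mr_mod
from . import network as net_mod
from . import preprocess as pre_mod
from . import screen as screen_mod
from . import select as select_mod
from .synthetic import CONFOUNDER_NAMES, MetaboMatrix

logger = logging.getLogger("metabosurv")

__all__ = ["PipelineConfig", "run_discovery", "run_validation", "stage_seed",
           "load_cohort_dir"]

_STAGES = ["simulate", "preprocess", "screen", "select", "model", "network",
           "mr", "mediate"]


@dataclass
class PipelineConfig:
    """All thresholds of the workflow, at their standard defaults: QC CV
    0.5, screening FDR 0.05, LASSO 10 folds x 200 repeats, stepwise
    retention P 0.1, network rho 0.1/0.2 at P < 0.01, MR instrument P 1e-5
    with LD r^2 < 0.001 in a 10,000 kb window, 1000 bootstrap replicates."""

    cohort_dir: str = "."
    out_dir: str = "results"
    endpoints: list = field(default_factory=lambda: ["death", "mace"])
    confounders: list = field(default_factory=lambda: list(CONFOUNDER_NAMES))
    cv_threshold: float = 0.5
    loess_span: float = 0.75
    fdr_threshold: float = 0.05
    lasso_folds: int = 10
    lasso_repeats: int = 200
    retention_p: float = 0.1
    rho_clinical: float = 0.1
    rho_metab: float = 0.2
    network_p: float = 0.01
    mr_p_threshold: float = 1e-5
    ld_r2: float = 0.001
    ld_window_kb: float = 10_000.0
    n_boot: int = 1000
    horizon: float | None = None      # None -> median follow-up
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**raw)


def stage_seed(master: int, stage: str) -> int:
    """Per-stage seed derived from the master seed (below 2^31)."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(master, spawn_key=(idx,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_cohort_dir(path) -> dict:
    """Load the TSV/JSON cohort layout written by the simulator (or
    assembled by hand in the same shape)."""
    path = Path(path)
    metab = pd.read_csv(path / "metabolites.tsv", sep="\t", index_col=0)
    samples = pd.read_csv(path / "samples.tsv", sep="\t")
    samples["is_qc"] = samples["is_qc"].astype(bool)
    out = {
        "metabolites": MetaboMatrix(intensities=metab, samples=samples),
        "clinical": pd.read_csv(path / "clinical.tsv", sep="\t", index_col=0),
        "outcomes": pd.read_csv(path / "outcomes.tsv", sep="\t", index_col=0),
    }
    for name, fn in [("genotypes", "genotypes.tsv"), ("snp_map", "snp_map.tsv"),
                     ("assoc", "assoc.tsv")]:
        p = path / fn
        if p.exists():
            out[name] = pd.read_csv(p, sep="\t",
                                    index_col=0 if name == "genotypes" else None)
    return out


def _endpoint_frame(outcomes: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    df = outcomes[[f"time_{endpoint}", f"event_{endpoint}"]].copy()
    df.columns = ["time", "event"]
    return df


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_discovery(config: PipelineConfig) -> dict:
    """Run the full discovery workflow; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort_dir(config.cohort_dir)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "inputs": {p.name: _sha256(p) for p in
                   sorted(Path(config.cohort_dir).glob("*.tsv"))},
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "stages": {},
    }

    def _write_manifest():
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=float)

    stage = "preprocess"
    try:
        logger.info("stage: preprocess")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm, qc_report = pre_mod.preprocess_pipeline(
                cohort["metabolites"], cv_threshold=config.cv_threshold,
                span=config.loess_span)
        norm.values.to_csv(out / "norm.tsv", sep="\t")
        qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        manifest["stages"]["preprocess"] = {
            "retained": int(qc_report["kept"].sum()),
            "total": int(len(qc_report))}

        stage = "screen"
        logger.info("stage: screen")
        conf = cohort["clinical"][config.confounders]
        X = screen_mod.standardize(norm.values)
        screens = {}
        candidates = {}
        for endpoint in config.endpoints:
            oc = _endpoint_frame(cohort["outcomes"], endpoint)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = screen_mod.cox_screen(X, oc, confounders=conf,
                                            already_standardized=True)
            res.to_csv(out / f"screen_{endpoint}.tsv", sep="\t", index=False)
            screens[endpoint] = res
            candidates[endpoint] = res.loc[res["fdr"] < config.fdr_threshold,
                                           "metabolite"].tolist()
        for trait in ("lvef", "lvmi"):
            if trait in cohort["outcomes"].columns:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = screen_mod.linear_screen(
                        X, cohort["outcomes"][trait], confounders=conf,
                        already_standardized=True)
                res.to_csv(out / f"screen_{trait}.tsv", sep="\t", index=False)
        manifest["stages"]["screen"] = {
            e: len(candidates[e]) for e in config.endpoints}

        stage = "select"
        logger.info("stage: select")
        signatures = {}
        for endpoint in config.endpoints:
            cand = candidates[endpoint]
            if not cand:
                warnings.warn(f"{endpoint}: no screening survivor; "
                              "clinical-only model downstream")
                signatures[endpoint] = []
                continue
            oc = _endpoint_frame(cohort["outcomes"], endpoint)
            sel = select_mod.stability_lasso_cox(
                X[cand], oc, confounders=conf, folds=config.lasso_folds,
                repeats=config.lasso_repeats,
                seed=manifest["stage_seeds"]["select"])
            sel.to_csv(out / f"signatures_{endpoint}.tsv", sep="\t", index=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                signatures[endpoint] = select_mod.select_signatures(sel)
        manifest["stages"]["select"] = {e: len(signatures[e])
                                        for e in config.endpoints}

        stage = "model"
        logger.info("stage: model")
        data = X.join(conf)
        models = {}
        for endpoint in config.endpoints:
            oc = _endpoint_frame(cohort["outcomes"], endpoint)
            fams = {
                "clinical": list(config.confounders),
                "metabolomic": list(signatures[endpoint]),
                "metabolomic+clinical": list(signatures[endpoint])
                + list(config.confounders),
            }
            t = config.horizon or float(oc["time"].median())
            ep_models = {}
            for fam, cand in fams.items():
                if not cand:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mdl = model_mod.stepwise_aic_cox(
                        data, cand, oc, retention_p=config.retention_p,
                        endpoint=endpoint)
                ep_models[fam] = mdl
            comparison = {}
            ref = ep_models.get("clinical")
            new = ep_models.get("metabolomic+clinical")
            if ref is not None and new is not None and ref.variables \
                    and new.variables:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    risk_new = model_mod.risk_at_horizon(new, data, t)
                    risk_ref = model_mod.risk_at_horizon(ref, data, t)
                    cmp_ = model_mod.reclassification_metrics(
                        risk_new, risk_ref, oc, t, n_boot=config.n_boot,
                        seed=manifest["stage_seeds"]["model"])
                comparison = dataclasses.asdict(cmp_)
            models[endpoint] = {"models": {f: m.to_dict()
                                           for f, m in ep_models.items()},
                                "horizon": t, "comparison": comparison}
        with open(out / "models.json", "w") as fh:
            json.dump(models, fh, indent=1, default=float)
        manifest["stages"]["model"] = {
            e: sorted(models[e]["models"]) for e in config.endpoints}

        stage = "network"
        logger.info("stage: network")
        assoc_mets = sorted(set().union(*candidates.values())) \
            if candidates else []
        clin_cont = [c for c in ("age", "sbp", "gluc", "chol", "hdlc", "syntax")
                     if c in cohort["clinical"].columns]
        clin = cohort["clinical"][clin_cont].join(
            cohort["outcomes"][["lvef", "lvmi"]])
        if assoc_mets:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                edges = net_mod.build_network(
                    X[assoc_mets], clin, rho_clinical=config.rho_clinical,
                    rho_metab=config.rho_metab, p_max=config.network_p)
        else:
            edges = pd.DataFrame(columns=["node_a", "node_b", "class_a",
                                          "class_b", "rho", "p"])
        edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
        net_mod.to_graphml(edges, out / "network.graphml")
        manifest["stages"]["network"] = {"edges": int(len(edges))}

        stage = "mr"
        logger.info("stage: mr")
        mr_rows = []
        mr_lvef_hits = []
        if "genotypes" in cohort and "assoc" in cohort:
            instruments = mr_mod.select_instruments(
                cohort["assoc"], p_threshold=config.mr_p_threshold)
            for met, cand in sorted(instruments.items()):
                if met not in X.columns:
                    continue
                pruned = mr_mod.ld_prune(
                    cand, cohort["genotypes"], cohort["snp_map"],
                    r2_max=config.ld_r2, window_kb=config.ld_window_kb)
                g = cohort["genotypes"][pruned["snp"].tolist()]
                for endpoint in config.endpoints:
                    oc = _endpoint_frame(cohort["outcomes"], endpoint)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est = mr_mod.two_stage_least_squares(
                            g, X[met], oc, "survival", exposure_name=met,
                            outcome_name=endpoint)
                    mr_rows.append(dataclasses.asdict(est))
                for trait in ("lvef", "lvmi"):
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est = mr_mod.two_stage_least_squares(
                            g, X[met], cohort["outcomes"][trait], "linear",
                            exposure_name=met, outcome_name=trait)
                    mr_rows.append(dataclasses.asdict(est))
                    if trait == "lvef" and est.p < 0.05:
                        mr_lvef_hits.append(met)
        mr_df = pd.DataFrame(mr_rows)
        mr_df.to_csv(out / "mr.tsv", sep="\t", index=False)
        manifest["stages"]["mr"] = {"estimates": int(len(mr_df)),
                                    "lvef_hits": mr_lvef_hits}

        stage = "mediate"
        logger.info("stage: mediate")
        y_bin = {e: cohort["outcomes"][f"event_{e}"].astype(float)
                 for e in config.endpoints}
        if mr_lvef_hits:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                med = med_mod.mediation_screen(
                    mr_lvef_hits, X, cohort["outcomes"]["lvef"], y_bin,
                    n_boot=config.n_boot,
                    seed=manifest["stage_seeds"]["mediate"])
        else:
            med = pd.DataFrame(columns=["metabolite", "endpoint",
                                        "proportion_pct", "p_total",
                                        "p_mediated", "reported"])
        med.to_csv(out / "mediation.tsv", sep="\t", index=False)
        manifest["stages"]["mediate"] = {"results": int(len(med))}
    except Exception as e:
        manifest["failed_stage"] = stage
        _write_manifest()
        raise StageFailure(stage, e) from e

    _write_manifest()
    return manifest


def run_validation(config: PipelineConfig, models_path, cohort_dir,
                   family: str = "metabolomic+clinical",
                   endpoint: str = "death") -> dict:
    """Apply frozen discovery coefficients to an independent cohort.

    Scores every validation sample with the discovery model's h(X) (aborting
    with a clear message if a model variable is absent from the validation
    features), stratifies by the validation cohort's own score quartiles,
    and reports the 3-group log-rank test plus a P < 0.05 replication screen
    of the model's metabolites.
    """
    with open(models_path) as fh:
        models = json.load(fh)
    spec = models[endpoint]["models"][family]
    coefs = pd.Series(spec["coefficients"], dtype=float)

    cohort = load_cohort_dir(cohort_dir)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm, _ = pre_mod.preprocess_pipeline(
            cohort["metabolites"], cv_threshold=config.cv_threshold,
            span=config.loess_span)
    X = screen_mod.standardize(norm.values).join(
        cohort["clinical"][config.confounders])
    shared = [v for v in coefs.index if v in X.columns]
    missing = [v for v in coefs.index if v not in X.columns]
    if missing:
        raise KeyError(
            f"model variable(s) absent from validation cohort: {missing}; "
            f"shared features: {len(shared)}/{len(coefs)}")
    scores = pd.Series(
        np.exp(X[coefs.index.tolist()].to_numpy(float) @ coefs.to_numpy()),
        index=X.index)
    oc = _endpoint_frame(cohort["outcomes"], endpoint)
    strat = model_mod.stratify_and_logrank(scores, oc)

    # replication screen at P < 0.05 for the model's metabolite variables
    mets = [v for v in coefs.index if v in norm.values.columns]
    repl = {}
    if mets:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = screen_mod.cox_screen(X[mets], oc, confounders=None,
                                        already_standardized=True)
        repl = {r["metabolite"]: bool(r["p"] < 0.05)
                for _, r in res.iterrows()}
    return {
        "endpoint": endpoint, "family": family,
        "n_validation": int(len(scores)),
        "logrank_p": strat.logrank_p, "logrank_stat": strat.logrank_stat,
        "q1": strat.q1, "q3": strat.q3,
        "group_sizes": strat.groups.value_counts().to_dict(),
        "replicated": repl,
        "shared_metabolites": int(
            len(set(norm.values.columns) & set(coefs.index))),
    }
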