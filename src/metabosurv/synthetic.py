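"""Synthetic cohort generator for the prognostic metabolomics pipeline.

Emulates the statistical structure of a targeted plasma-metabolomics survival
study in coronary artery disease: a samples x metabolites intensity matrix with
batch offsets, within-batch injection-order drift and periodic pooled-QC
injections; below-LOD left-censoring; a 17-covariate clinical confounder table;
censored survival endpoints (all-cause death and MACE, death being a subset of
MACE) generated from a Weibull proportional-hazards model in which metabolite
effects are partly mediated through LVEF; and additive-coded SNP genotypes in
Hardy-Weinberg proportions acting as instruments on metabolites.

Every draw derives from a single master seed, so a cohort is bit-reproducible.
The generating parameters ("truth") are carried alongside the data and
serialized to a sidecar JSON so downstream recovery tests never re-derive them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortConfig",
    "MetaboMatrix",
    "SurvivalOutcome",
    "SyntheticCohort",
    "generate_metabolome",
    "generate_genotypes",
    "generate_outcomes",
    "simulate_cohort",
    "snp_metabolite_assoc",
    "CONFOUNDER_NAMES",
]

# The 17 clinical confounders used in the adjusted analyses.
CONFOUNDER_NAMES = [
    "age", "sex", "ast", "egfr", "diabetes", "hypertension", "sbp", "gluc",
    "chol", "hdlc", "ppi", "acei", "beta_blocker", "ccb", "current_smoking",
    "family_history_cvd", "syntax",
]
_BINARY_CONFOUNDERS = {
    "sex": 0.75, "diabetes": 0.30, "hypertension": 0.55, "ppi": 0.30,
    "acei": 0.40, "beta_blocker": 0.60, "ccb": 0.30, "current_smoking": 0.25,
    "family_history_cvd": 0.10,
}
_CONTINUOUS_CONFOUNDERS = {
    # name: (mean, sd)
    "age": (63.0, 10.0), "ast": (25.0, 8.0), "egfr": (85.0, 20.0),
    "sbp": (130.0, 18.0), "gluc": (5.8, 1.5), "chol": (4.5, 1.0),
    "hdlc": (1.1, 0.3), "syntax": (15.0, 8.0),
}


def _default_hazard_effects() -> dict:
    # Four signature metabolites with a modest per-SD hazard, both endpoints.
    b = float(np.log(1.5))
    return {f"met_{i:04d}": {"death": b, "mace": b} for i in range(1, 5)}


def _default_mediator_effects() -> dict:
    # The same four signatures depress LVEF by 2 percentage points per SD.
    return {f"met_{i:04d}": -2.0 for i in range(1, 5)}


def _default_instrument_effects() -> dict:
    # Three SNPs instrument the first signature metabolite at 0.3 SD/allele.
    return {"met_0001": (["rs0001", "rs0002", "rs0003"], 0.3)}


@dataclass
class CohortConfig:
    """Generating parameters of a synthetic cohort.

    Defaults emulate the discovery-cohort conditions the pipeline is designed
    for: 1040 patients, 202 targeted metabolites, periodic pooled-QC
    injections, injection-order drift, below-LOD censoring, and event counts
    on the order of 60 deaths / 180 MACEs over a median ~3.5 years of
    follow-up.

    Parameters
    ----------
    drift_amplitude : fractional intensity ramp across each batch (0.3 = +30%).
    noise_cv : analytical (technical) coefficient of variation.
    biological_cv : between-subject lognormal CV of the study samples.
    lod_quantile : fraction of values left-censored below the detection limit.
    instrument_effects : metabolite -> (list of SNP ids, per-allele effect in
        SD units of the latent metabolite).
    hazard_effects : metabolite -> {"death": log-HR/SD, "mace": log-HR/SD}.
    mediator_effects : metabolite -> LVEF change (percentage points) per SD.
    mediator_hazard : log-HR per LVEF percentage point (negative: low LVEF is
        harmful).
    baseline_hazard : (Weibull shape, scale in years) of the death endpoint.
    nonfatal_hazard_scale : Weibull scale of the non-fatal MACE component
        (same shape); MACE time = min(death time, non-fatal time), so death
        events are a subset of MACE events by construction.
    censor_rate : per-year exponential loss-to-follow-up rate; administrative
        censoring is uniform on (0.1, followup_max) to mimic staggered entry.
    confounding_strength : loading of (standardized) age and diabetes on a
        subset of metabolites, making confounder adjustment non-trivial.
    """

    n_samples: int = 1040
    n_metabolites: int = 202
    n_batches: int = 4
    qc_every: int = 10
    drift_amplitude: float = 0.3
    noise_cv: float = 0.1
    biological_cv: float = 0.35
    batch_sd: float = 0.15
    lod_quantile: float = 0.03
    n_snps: int = 30
    maf_range: tuple = (0.1, 0.5)
    snp_spacing_bp: int = 1_000_000
    ld_blocks: list | None = None
    ld_flip_prob: float = 0.05
    instrument_effects: dict = field(default_factory=_default_instrument_effects)
    hazard_effects: dict = field(default_factory=_default_hazard_effects)
    mediator_effects: dict = field(default_factory=_default_mediator_effects)
    mediator_hazard: float = -0.05
    lvef_intercept: float = 60.0
    lvef_noise_sd: float = 5.0
    baseline_hazard: tuple = (1.2, 75.0)
    nonfatal_hazard_scale: float = 30.0
    censor_rate: float = 0.02
    followup_max: float = 7.0
    confounding_strength: float = 0.2
    confounder_log_hr: float = 0.35
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0 or self.n_metabolites <= 0:
            raise ValueError("n_samples and n_metabolites must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.drift_amplitude < 0:
            raise ValueError("drift_amplitude must be >= 0")

    @property
    def metabolite_names(self) -> list:
        return [f"met_{i:04d}" for i in range(1, self.n_metabolites + 1)]

    @property
    def snp_names(self) -> list:
        return [f"rs{i:04d}" for i in range(1, self.n_snps + 1)]


@dataclass
class MetaboMatrix:
    """Raw intensity matrix with its sample annotation.

    ``intensities``: rows = injections (study + QC), columns = metabolites;
    NaN marks below-LOD values. ``samples``: sample_id, batch,
    injection_order, is_qc.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame

    @property
    def qc_mask(self) -> pd.Series:
        return self.samples.set_index("sample_id")["is_qc"].reindex(self.intensities.index)

    def study(self) -> pd.DataFrame:
        """Intensity rows of study (non-QC) samples."""
        return self.intensities.loc[~self.qc_mask.values]

    def qc(self) -> pd.DataFrame:
        return self.intensities.loc[self.qc_mask.values]


@dataclass
class SurvivalOutcome:
    """Per-sample endpoint table: (time, event) for death and MACE plus
    continuous remodeling traits (LVEF %, LVMI g/m2)."""

    table: pd.DataFrame  # index sample_id; columns time_death, event_death, time_mace, event_mace, lvef, lvmi

    def endpoint(self, name: str) -> pd.DataFrame:
        if name not in ("death", "mace"):
            raise ValueError(f"unknown endpoint {name!r}")
        out = self.table[[f"time_{name}", f"event_{name}"]].copy()
        out.columns = ["time", "event"]
        return out


@dataclass
class SyntheticCohort:
    metabolites: MetaboMatrix
    clinical: pd.DataFrame
    outcomes: SurvivalOutcome
    genotypes: pd.DataFrame        # samples x SNPs, additive 0/1/2
    snp_map: pd.DataFrame          # snp, chrom, pos_bp (1-based)
    assoc: pd.DataFrame            # snp, metabolite, beta, se, p (first-stage style)
    latent: pd.DataFrame           # SD-unit latent metabolite matrix (truth-side)
    truth: dict

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.metabolites.intensities.to_csv(path / "metabolites.tsv", sep="\t")
        self.metabolites.samples.to_csv(path / "samples.tsv", sep="\t", index=False)
        self.clinical.to_csv(path / "clinical.tsv", sep="\t")
        self.outcomes.table.to_csv(path / "outcomes.tsv", sep="\t")
        self.genotypes.to_csv(path / "genotypes.tsv", sep="\t")
        self.snp_map.to_csv(path / "snp_map.tsv", sep="\t", index=False)
        self.assoc.to_csv(path / "assoc.tsv", sep="\t", index=False)
        with open(path / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, default=float)


def _sample_table(config: CohortConfig) -> pd.DataFrame:
    """Injection layout: study samples split across batches, one pooled-QC
    injection every ``qc_every`` study injections (plus one leading QC per
    batch so drift curves are anchored at the block start)."""
    per_batch = np.full(config.n_batches, config.n_samples // config.n_batches)
    per_batch[: config.n_samples % config.n_batches] += 1
    if config.qc_every >= per_batch.min():
        raise ValueError(
            f"qc_every={config.qc_every} >= smallest batch size {per_batch.min()}: "
            "no QC coverage within a batch"
        )
    rows = []
    order = 0
    s_idx = 0
    for b in range(config.n_batches):
        q_idx = 0
        for j in range(per_batch[b]):
            if j % config.qc_every == 0:
                order += 1
                q_idx += 1
                rows.append((f"QC_b{b + 1}_{q_idx:03d}", b + 1, order, True))
            order += 1
            s_idx += 1
            rows.append((f"S{s_idx:04d}", b + 1, order, False))
        order += 1
        q_idx += 1
        rows.append((f"QC_b{b + 1}_{q_idx:03d}", b + 1, order, True))  # closing QC
    return pd.DataFrame(rows, columns=["sample_id", "batch", "injection_order", "is_qc"])


def _confounders(config: CohortConfig, rng: np.random.Generator, ids) -> pd.DataFrame:
    n = len(ids)
    cols = {}
    for name in CONFOUNDER_NAMES:
        if name in _BINARY_CONFOUNDERS:
            cols[name] = rng.binomial(1, _BINARY_CONFOUNDERS[name], n).astype(float)
        else:
            mu, sd = _CONTINUOUS_CONFOUNDERS[name]
            cols[name] = rng.normal(mu, sd, n)
    df = pd.DataFrame(cols, index=pd.Index(ids, name="sample_id"))
    df["syntax"] = df["syntax"].clip(lower=0.0)
    df["egfr"] = df["egfr"].clip(lower=10.0)
    return df


def _latent_metabolites(config: CohortConfig, rng: np.random.Generator,
                        clinical: pd.DataFrame, genotypes: pd.DataFrame) -> pd.DataFrame:
    """SD-unit latent biological levels driving outcomes and instruments."""
    n = clinical.shape[0]
    m = config.n_metabolites
    z = rng.standard_normal((n, m))
    names = config.metabolite_names
    if config.confounding_strength > 0:
        age_std = (clinical["age"].to_numpy() - _CONTINUOUS_CONFOUNDERS["age"][0]) / \
            _CONTINUOUS_CONFOUNDERS["age"][1]
        diab = clinical["diabetes"].to_numpy()
        # age / diabetes load onto every third metabolite
        loaded = np.arange(0, m, 3)
        z[:, loaded] += config.confounding_strength * age_std[:, None]
        z[:, loaded[::2]] += config.confounding_strength * diab[:, None]
    zdf = pd.DataFrame(z, index=clinical.index, columns=names)
    for met, (snps, eff) in config.instrument_effects.items():
        if met not in zdf.columns:
            raise ValueError(f"instrument target {met!r} not among metabolites")
        for snp in snps:
            zdf[met] = zdf[met] + eff * genotypes[snp].to_numpy()
    return zdf


def generate_metabolome(config: CohortConfig, latent: pd.DataFrame | None = None,
                        rng: np.random.Generator | None = None) -> MetaboMatrix:
    """Raw intensity matrix with batch offsets, injection-order drift,
    analytical noise and below-LOD missingness.

    intensity(s, m) = baseline_m * batch_factor(batch_s, m)
                      * (1 + drift(position in batch)) * exp(sigma * latent)
                      * lognormal analytical noise

    QC injections draw from a fixed pooled profile (latent term = 0).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    samples = _sample_table(config)
    n_rows = len(samples)
    m = config.n_metabolites
    names = config.metabolite_names

    baseline = np.exp(rng.uniform(np.log(1e3), np.log(1e6), m))
    batch_factor = np.exp(rng.normal(0.0, config.batch_sd, (config.n_batches, m)))
    sigma_bio = float(np.sqrt(np.log1p(config.biological_cv ** 2)))
    sigma_noise = float(np.sqrt(np.log1p(config.noise_cv ** 2)))

    # position of each injection within its batch, scaled to [0, 1]
    pos = np.empty(n_rows)
    for b, grp in samples.groupby("batch"):
        o = grp["injection_order"].to_numpy()
        pos[grp.index] = (o - o.min()) / max(o.max() - o.min(), 1)
    drift = 1.0 + config.drift_amplitude * pos

    log_i = np.log(baseline)[None, :] \
        + np.log(batch_factor)[samples["batch"].to_numpy() - 1, :] \
        + np.log(drift)[:, None]
    if sigma_noise > 0:
        log_i = log_i + rng.normal(0.0, sigma_noise, (n_rows, m))
    study_rows = np.flatnonzero(~samples["is_qc"].to_numpy())
    if latent is None:
        latent_arr = rng.standard_normal((len(study_rows), m))
    else:
        latent_arr = latent.to_numpy()
    log_i[study_rows, :] += sigma_bio * latent_arr

    intens = np.exp(log_i)
    if config.lod_quantile > 0:
        lod = np.quantile(intens, config.lod_quantile, axis=0)
        intens = np.where(intens < lod[None, :], np.nan, intens)
    df = pd.DataFrame(intens, index=pd.Index(samples["sample_id"], name="sample_id"),
                      columns=names)
    return MetaboMatrix(intensities=df, samples=samples)


def generate_genotypes(config: CohortConfig, ids,
                       rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Additive 0/1/2 genotype matrix in Hardy-Weinberg proportions, with
    optional LD blocks by copy-with-mutation, and a (snp, chrom, pos_bp) map."""
    if config.n_snps <= 0:
        raise ValueError("n_snps must be positive")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n = len(ids)
    names = config.snp_names
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], config.n_snps)
    geno = np.column_stack([rng.binomial(2, p, n) for p in mafs]).astype(float)
    gdf = pd.DataFrame(geno, index=pd.Index(ids, name="sample_id"), columns=names)

    pos = (np.arange(config.n_snps) + 1) * config.snp_spacing_bp
    snp_map = pd.DataFrame({"snp": names, "chrom": "1", "pos_bp": pos})
    if config.ld_blocks:
        pos_s = snp_map.set_index("snp")["pos_bp"].copy()
        for block in config.ld_blocks:
            anchor = block[0]
            for k, snp in enumerate(block[1:], start=1):
                hap = gdf[anchor].to_numpy().copy()
                flip = rng.random(n) < config.ld_flip_prob
                hap[flip] = rng.binomial(2, mafs[names.index(snp)], flip.sum())
                gdf[snp] = hap
                pos_s[snp] = pos_s[anchor] + 10_000 * k  # co-locate block members
        snp_map["pos_bp"] = snp_map["snp"].map(pos_s).to_numpy()
    return gdf, snp_map


def generate_outcomes(latent: pd.DataFrame, clinical: pd.DataFrame,
                      config: CohortConfig,
                      rng: np.random.Generator | None = None) -> SurvivalOutcome:
    """Censored survival endpoints and remodeling traits.

    LVEF = intercept + sum(mediator_effects * latent metabolite) + noise;
    log-hazard = direct metabolite effects + mediator_hazard * (LVEF -
    intercept) + confounder terms; death and non-fatal event times are
    Weibull-PH draws and MACE = min of the two, so observed deaths are a
    subset of observed MACEs.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    n = latent.shape[0]

    lvef = np.full(n, config.lvef_intercept)
    for met, eff in config.mediator_effects.items():
        lvef = lvef + eff * latent[met].to_numpy()
    lvef = lvef + rng.normal(0.0, config.lvef_noise_sd, n)
    lvmi = 95.0 - 0.8 * (lvef - config.lvef_intercept) + rng.normal(0.0, 12.0, n)

    age_std = (clinical["age"].to_numpy() - _CONTINUOUS_CONFOUNDERS["age"][0]) / \
        _CONTINUOUS_CONFOUNDERS["age"][1]
    conf_term = config.confounder_log_hr * age_std \
        + config.confounder_log_hr * clinical["diabetes"].to_numpy()

    def _eta(endpoint: str) -> np.ndarray:
        e = np.zeros(n)
        for met, effs in config.hazard_effects.items():
            b = effs[endpoint] if isinstance(effs, dict) else float(effs)
            e += b * latent[met].to_numpy()
        e += config.mediator_hazard * (lvef - config.lvef_intercept)
        e += conf_term
        if not np.all(np.isfinite(e)):
            bad = latent.index[~np.isfinite(e)][0]
            raise ValueError(f"non-finite log-hazard for sample {bad!r}")
        return e

    shape, scale_d = config.baseline_hazard

    def _weibull_times(eta: np.ndarray, scale: float) -> np.ndarray:
        u = rng.uniform(size=n)
        return scale * (-np.log(u) / np.exp(eta)) ** (1.0 / shape)

    t_death = _weibull_times(_eta("death"), scale_d)
    t_nonfatal = _weibull_times(_eta("mace"), config.nonfatal_hazard_scale)
    t_mace = np.minimum(t_death, t_nonfatal)

    cens = rng.uniform(0.1, config.followup_max, n)
    if config.censor_rate > 0:
        cens = np.minimum(cens, rng.exponential(1.0 / config.censor_rate, n))

    tab = pd.DataFrame(index=latent.index)
    tab["time_death"] = np.minimum(t_death, cens)
    tab["event_death"] = (t_death <= cens).astype(int)
    tab["time_mace"] = np.minimum(t_mace, cens)
    tab["event_mace"] = (t_mace <= cens).astype(int)
    tab["lvef"] = lvef
    tab["lvmi"] = lvmi
    return SurvivalOutcome(table=tab)


def snp_metabolite_assoc(genotypes: pd.DataFrame, latent: pd.DataFrame) -> pd.DataFrame:
    """All-pairs simple-regression summary statistics (SNP -> metabolite),
    in the layout of an external metabolome-GWAS summary table:
    snp, metabolite, beta, se, p. Vectorized OLS with an intercept."""
    g = genotypes.to_numpy(dtype=float)
    z = latent.to_numpy(dtype=float)
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    zc = z - z.mean(axis=0)
    sgg = (gc ** 2).sum(axis=0)                      # (k,)
    beta = (gc.T @ zc) / sgg[:, None]                # (k, m)
    resid_ss = (zc ** 2).sum(axis=0)[None, :] - beta ** 2 * sgg[:, None]
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / sgg[:, None])
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    rows = pd.DataFrame({
        "snp": np.repeat(genotypes.columns.to_numpy(), z.shape[1]),
        "metabolite": np.tile(latent.columns.to_numpy(), g.shape[1]),
        "beta": beta.ravel(),
        "se": se.ravel(),
        "p": p.ravel(),
    })
    return rows


def _truth(config: CohortConfig) -> dict:
    """Generating parameters and their closed-form implications."""
    mh = config.mediator_hazard
    med = {}
    for met, effs in config.hazard_effects.items():
        a = config.mediator_effects.get(met, 0.0)
        for endpoint in ("death", "mace"):
            direct = effs[endpoint] if isinstance(effs, dict) else float(effs)
            indirect = a * mh
            total = direct + indirect
            med[f"{met}:{endpoint}"] = {
                "direct": direct, "indirect": indirect, "total": total,
                "proportion_mediated": indirect / total if total != 0 else float("nan"),
            }
    return {
        "config": {k: v for k, v in dataclasses.asdict(config).items()},
        "signature_metabolites": sorted(config.hazard_effects),
        "instrument_effects": {m: [list(s), e] for m, (s, e) in
                               config.instrument_effects.items()},
        "mediation": med,
    }


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Full cohort: clinical table, genotypes, latent metabolite levels, raw
    intensities and outcomes, all from the config's master seed."""
    ss = np.random.SeedSequence(config.seed)
    r_clin, r_geno, r_latent, r_metab, r_out = \
        [np.random.default_rng(s) for s in ss.spawn(5)]

    layout = _sample_table(config)
    study_ids = layout.loc[~layout["is_qc"], "sample_id"].tolist()
    clinical = _confounders(config, r_clin, study_ids)
    genotypes, snp_map = generate_genotypes(config, study_ids, rng=r_geno)
    # latent biological levels (SD units, plus confounder + instrument shifts)
    latent = _latent_metabolites(
        dataclasses.replace(config), r_latent, clinical, genotypes)
    metab = generate_metabolome(config, latent=latent, rng=r_metab)
    outcomes = generate_outcomes(latent, clinical, config, rng=r_out)
    assoc = snp_metabolite_assoc(genotypes, latent)
    return SyntheticCohort(
        metabolites=metab, clinical=clinical, outcomes=outcomes,
        genotypes=genotypes, snp_map=snp_map, assoc=assoc, latent=latent,
        truth=_truth(config),
    )
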