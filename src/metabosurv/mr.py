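"""One-sample Mendelian randomisation by two-stage least squares.

Instruments for each metabolite are SNPs from an external SNP-metabolite
summary table passing P < 1e-5, LD-pruned greedily by ascending P at
r^2 < 0.001 within a 10,000 kb window (SNPs farther apart are treated as
independent). Stage 1 regresses the exposure on all retained instruments
jointly; stage 2 regresses the outcome on the fitted exposure — Cox
proportional hazards (Efron ties) for death/MACE, OLS for LVEF/LVMI.

Second-stage standard errors condition on the first-stage fit (the
generated-regressor caveat); a nonparametric bootstrap over samples is
available for SEs that propagate first-stage uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "InstrumentSet", "CausalEstimate",
    "select_instruments", "ld_prune", "two_stage_least_squares",
    "read_genotypes_tsv", "read_genotypes_vcf",
]


@dataclass
class InstrumentSet:
    metabolite: str
    snps: pd.DataFrame          # snp, beta, se, p (first-stage summary)
    f_statistic: float | None = None


@dataclass
class CausalEstimate:
    exposure: str
    outcome: str                # death | mace | lvef | lvmi
    outcome_type: str           # survival | linear
    effect: float               # HR for survival, slope for linear
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_instruments: int
    f_statistic: float


def select_instruments(assoc: pd.DataFrame, p_threshold: float = 1e-5
                       ) -> dict[str, pd.DataFrame]:
    """Candidate instruments per metabolite: SNPs with association P below
    the genome-wide-suggestive threshold (default 1e-5). Metabolites with no
    passing SNP are omitted (skipped downstream with a notice)."""
    need = {"snp", "metabolite", "beta", "se", "p"}
    if not need.issubset(assoc.columns):
        raise ValueError(f"association table must have columns {sorted(need)}")
    hits = assoc.loc[assoc["p"] < p_threshold]
    out = {}
    for met, grp in hits.groupby("metabolite"):
        out[met] = grp.sort_values("p").reset_index(drop=True)
    return out


def _ld_r2(g: pd.DataFrame, a: str, b: str) -> float:
    """Pearson r^2 between additive dosages; missing genotypes mean-imputed."""
    x = g[a].to_numpy(float)
    y = g[b].to_numpy(float)
    x = np.where(np.isnan(x), np.nanmean(x), x)
    y = np.where(np.isnan(y), np.nanmean(y), y)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def ld_prune(candidates: pd.DataFrame, genotypes: pd.DataFrame,
             snp_map: pd.DataFrame, r2_max: float = 0.001,
             window_kb: float = 10_000.0) -> pd.DataFrame:
    """Greedy LD pruning by ascending P.

    A candidate is kept iff its r^2 with every already-kept SNP on the same
    chromosome within ``window_kb`` is below ``r2_max``; SNPs beyond the
    window (or on other chromosomes) are always mutually independent. The
    result is independent of input order (sorting by P is internal).
    """
    missing = [s for s in candidates["snp"] if s not in genotypes.columns]
    if missing:
        raise KeyError(f"genotype column(s) missing for SNP(s): {missing}")
    pos = snp_map.set_index("snp")
    cand = candidates.sort_values(["p", "snp"]).reset_index(drop=True)
    kept: list[str] = []
    for _, row in cand.iterrows():
        snp = row["snp"]
        ok = True
        for k in kept:
            same_chrom = str(pos.loc[snp, "chrom"]) == str(pos.loc[k, "chrom"])
            dist_kb = abs(float(pos.loc[snp, "pos_bp"]) -
                          float(pos.loc[k, "pos_bp"])) / 1000.0
            if same_chrom and dist_kb <= window_kb:
                if _ld_r2(genotypes, snp, k) >= r2_max:
                    ok = False
                    break
        if ok:
            kept.append(snp)
    return cand.loc[cand["snp"].isin(kept)].reset_index(drop=True)


def _first_stage(genotypes: pd.DataFrame, exposure: pd.Series
                 ) -> tuple[pd.Series, float, pd.DataFrame]:
    """OLS of exposure on all instruments jointly; returns fitted exposure,
    the joint first-stage F statistic, and the genotype design actually used
    (collinear instruments dropped with a warning)."""
    g = genotypes.loc[exposure.index].astype(float)
    # drop collinear instruments
    keep = []
    for c in g.columns:
        trial = g[keep + [c]].to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(g)), trial])) \
                == len(keep) + 2:
            keep.append(c)
        else:
            warnings.warn(f"dropping collinear instrument {c!r}")
    g = g[keep]
    fit = sm.OLS(exposure.to_numpy(float), sm.add_constant(g.to_numpy())).fit()
    fitted = pd.Series(fit.fittedvalues, index=exposure.index, name="xhat")
    f_stat = float(fit.fvalue)
    if f_stat < 10:
        warnings.warn(f"weak instruments: first-stage F = {f_stat:.2f} < 10")
    return fitted, f_stat, g


def two_stage_least_squares(genotypes: pd.DataFrame, exposure: pd.Series,
                            outcome, outcome_type: str,
                            covariates: pd.DataFrame | None = None,
                            exposure_name: str = "exposure",
                            outcome_name: str = "outcome",
                            n_boot: int = 0, seed: int = 0) -> CausalEstimate:
    """2SLS causal estimate of an exposure on an outcome.

    Parameters
    ----------
    genotypes : samples x instrument-SNPs additive dosages.
    exposure : metabolite level (SD units) per sample.
    outcome : for ``outcome_type="survival"``, a DataFrame with columns
        ``time`` and ``event``; for ``"linear"``, a Series.
    covariates : optional covariates entering stage 2.
    n_boot : if > 0, replace the conditional SE by a nonparametric bootstrap
        re-running both stages on resampled rows.
    """
    if outcome_type not in ("survival", "linear"):
        raise ValueError("outcome_type must be 'survival' or 'linear'")
    xhat, f_stat, g_used = _first_stage(genotypes, exposure)
    if xhat.std() == 0:
        raise ValueError("fitted exposure has zero variance: instruments "
                         "carry no signal")
    est = _second_stage(xhat, outcome, outcome_type, covariates)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        idx = np.arange(len(xhat))
        for _ in range(n_boot):
            bi = rng.integers(0, len(idx), len(idx))
            rows = exposure.index[bi]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    xh_b = _first_stage(
                        g_used.iloc[bi].reset_index(drop=True),
                        exposure.iloc[bi].reset_index(drop=True))[0]
                    if outcome_type == "survival":
                        out_b = outcome.loc[rows].reset_index(drop=True)
                    else:
                        out_b = outcome.iloc[bi].reset_index(drop=True)
                    cov_b = None if covariates is None else \
                        covariates.iloc[bi].reset_index(drop=True)
                    boots.append(_second_stage(xh_b, out_b, outcome_type,
                                               cov_b)["beta"])
            except Exception:
                continue
        if len(boots) >= 10:
            est["se"] = float(np.std(boots, ddof=1))
            est["ci"] = (float(np.percentile(boots, 2.5)),
                         float(np.percentile(boots, 97.5)))
    beta, se = est["beta"], est["se"]
    lo, hi = est["ci"]
    if outcome_type == "survival":
        effect, ci_low, ci_high = np.exp(beta), np.exp(lo), np.exp(hi)
    else:
        effect, ci_low, ci_high = beta, lo, hi
    return CausalEstimate(
        exposure=exposure_name, outcome=outcome_name, outcome_type=outcome_type,
        effect=float(effect), se=float(se), ci_low=float(ci_low),
        ci_high=float(ci_high), p=float(est["p"]),
        n_instruments=g_used.shape[1], f_statistic=f_stat,
    )


def _second_stage(xhat: pd.Series, outcome, outcome_type: str,
                  covariates: pd.DataFrame | None) -> dict:
    if outcome_type == "survival":
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"xhat": xhat})
        if covariates is not None:
            df = df.join(covariates.set_axis(xhat.index)
                         if not covariates.index.equals(xhat.index)
                         else covariates)
        df = df.join(outcome[["time", "event"]].set_axis(xhat.index)
                     if not outcome.index.equals(xhat.index) else
                     outcome[["time", "event"]])
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        s = cph.summary.loc["xhat"]
        return {"beta": float(s["coef"]), "se": float(s["se(coef)"]),
                "ci": (float(s["coef lower 95%"]), float(s["coef upper 95%"])),
                "p": float(s["p"])}
    y = np.asarray(outcome, float)
    design = pd.DataFrame({"xhat": xhat.to_numpy()})
    if covariates is not None:
        design = pd.concat([design,
                            covariates.reset_index(drop=True)], axis=1)
    fit = sm.OLS(y, sm.add_constant(design.to_numpy(float))).fit()
    ci = fit.conf_int()[1]
    return {"beta": float(fit.params[1]), "se": float(fit.bse[1]),
            "ci": (float(ci[0]), float(ci[1])), "p": float(fit.pvalues[1])}


def genotype_pcs(genotypes: pd.DataFrame, n_components: int = 10) -> pd.DataFrame:
    """Top principal components of the (standardized, mean-imputed) genotype
    matrix, for population-structure adjustment in stage-2 covariate sets."""
    g = genotypes.to_numpy(float)
    g = np.where(np.isnan(g), np.nanmean(g, axis=0), g)
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    g = g / np.where(sd == 0, 1.0, sd)
    n_components = min(n_components, min(g.shape) - 1)
    u, s, _ = np.linalg.svd(g, full_matrices=False)
    pcs = u[:, :n_components] * s[:n_components]
    return pd.DataFrame(pcs, index=genotypes.index,
                        columns=[f"PC{i + 1}" for i in range(n_components)])


def read_genotypes_tsv(path, snp_map_path=None) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Additive-coded genotype TSV (samples x SNPs) with an optional sidecar
    map (snp, chrom, pos_bp, 1-based)."""
    g = pd.read_csv(path, sep="\t", index_col=0)
    snp_map = None
    if snp_map_path is not None:
        snp_map = pd.read_csv(snp_map_path, sep="\t")
    return g, snp_map


def read_genotypes_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into an additive dosage matrix plus (snp, chrom, pos_bp)
    map. Missing genotypes become NaN."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, rows = {}, []
    for var in vcf:
        snp = var.ID or f"{var.CHROM}:{var.POS}"
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom-ref,1=het,2=unknown,3=hom-alt
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        cols[snp] = dosage
        rows.append((snp, str(var.CHROM), int(var.POS)))
    g = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    snp_map = pd.DataFrame(rows, columns=["snp", "chrom", "pos_bp"])
    return g, snp_map
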