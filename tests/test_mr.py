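"""Mendelian randomisation: instrument selection, LD pruning, 2SLS."""

import numpy as np
import pandas as pd
import pytest

from metabosurv import (
    CohortConfig,
    ld_prune,
    select_instruments,
    simulate_cohort,
    two_stage_least_squares,
)

from conftest import surv_frame


def _assoc(rows):
    return pd.DataFrame(rows, columns=["snp", "metabolite", "beta", "se", "p"])


class TestSelectInstruments:
    def test_threshold_is_strict(self):
        assoc = _assoc([("rs1", "metA", 0.3, 0.05, 1e-4),
                        ("rs2", "metA", 0.3, 0.05, 1e-6),
                        ("rs3", "metB", 0.2, 0.05, 0.5)])
        out = select_instruments(assoc, p_threshold=1e-5)
        assert list(out["metA"]["snp"]) == ["rs2"]
        assert "metB" not in out

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            select_instruments(pd.DataFrame({"snp": [], "p": []}))

    def test_true_instruments_recovered_from_generator(self):
        hits = 0
        for seed in range(10):
            cfg = CohortConfig(
                n_samples=5000, n_metabolites=5, n_snps=6, seed=seed,
                instrument_effects={"met_0001": (["rs0001", "rs0002",
                                                  "rs0003"], 0.3)},
                hazard_effects={}, mediator_effects={})
            coh = simulate_cohort(cfg)
            sel = select_instruments(coh.assoc, p_threshold=1e-5)
            got = set(sel.get("met_0001", pd.DataFrame({"snp": []}))["snp"])
            hits += got == {"rs0001", "rs0002", "rs0003"}
        assert hits >= 9


class TestLdPrune:
    @staticmethod
    def _map(snps, pos):
        return pd.DataFrame({"snp": snps, "chrom": "1", "pos_bp": pos})

    @staticmethod
    def _geno(cols, n=400, seed=0, r2_pairs=()):
        rng = np.random.default_rng(seed)
        g = {c: rng.binomial(2, 0.3, n).astype(float) for c in cols}
        for a, b, noise in r2_pairs:
            flip = rng.random(n) < noise
            g[b] = np.where(flip, rng.binomial(2, 0.3, n), g[a])
        return pd.DataFrame(g)

    def test_correlated_pair_keeps_lower_p(self):
        g = self._geno(["rs1", "rs2"], r2_pairs=[("rs1", "rs2", 0.2)])
        cand = _assoc([("rs1", "m", 0.3, 0.05, 1e-8),
                       ("rs2", "m", 0.3, 0.05, 1e-6)])
        kept = ld_prune(cand, g, self._map(["rs1", "rs2"], [1000, 2000]))
        assert list(kept["snp"]) == ["rs1"]

    def test_beyond_window_both_kept(self):
        g = self._geno(["rs1", "rs2"], r2_pairs=[("rs1", "rs2", 0.01)])
        cand = _assoc([("rs1", "m", 0.3, 0.05, 1e-8),
                       ("rs2", "m", 0.3, 0.05, 1e-6)])
        # 20,000 kb apart: outside the 10,000 kb window despite r2 ~ 1
        snp_map = self._map(["rs1", "rs2"], [1, 20_000_000_001])
        kept = ld_prune(cand, g, snp_map)
        assert set(kept["snp"]) == {"rs1", "rs2"}

    def test_single_block_leaves_minimum_p(self):
        cols = [f"rs{i}" for i in range(10)]
        pairs = [("rs0", c, 0.02) for c in cols[1:]]
        g = self._geno(cols, r2_pairs=pairs)
        rng = np.random.default_rng(1)
        ps = rng.uniform(1e-10, 1e-6, 10)
        cand = _assoc([(c, "m", 0.3, 0.05, p) for c, p in zip(cols, ps)])
        snp_map = self._map(cols, 1000 + 10_000 * np.arange(10))
        kept = ld_prune(cand, g, snp_map)
        assert list(kept["snp"]) == [cols[int(np.argmin(ps))]]

    def test_order_independent(self):
        cols = ["rs1", "rs2", "rs3"]
        g = self._geno(cols, r2_pairs=[("rs1", "rs2", 0.05)])
        cand = _assoc([("rs3", "m", 0.2, 0.05, 1e-7),
                       ("rs1", "m", 0.3, 0.05, 1e-9),
                       ("rs2", "m", 0.3, 0.05, 1e-8)])
        snp_map = self._map(cols, [1000, 2000, 3000])
        a = ld_prune(cand, g, snp_map)
        b = ld_prune(cand.iloc[::-1].reset_index(drop=True), g, snp_map)
        assert list(a["snp"]) == list(b["snp"])

    def test_missing_genotype_column_named(self):
        g = self._geno(["rs1"])
        cand = _assoc([("rs1", "m", 0.3, 0.05, 1e-8),
                       ("rsX", "m", 0.3, 0.05, 1e-8)])
        with pytest.raises(KeyError, match="rsX"):
            ld_prune(cand, g, self._map(["rs1", "rsX"], [1, 2]))


def _confounded(n=5000, seed=0, causal=0.5, k=5):
    """Confounded exposure-outcome pair with strong, clean instruments
    (joint first-stage F in the hundreds, so the 2SLS sampling SE is well
    below the recovery tolerance)."""
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, (n, k)).astype(float)
    u = rng.standard_normal(n)
    x = g @ np.full(k, 0.5) + u + rng.standard_normal(n)
    y = causal * x + 1.0 * u + rng.standard_normal(n)
    idx = pd.Index([f"S{i}" for i in range(n)])
    G = pd.DataFrame(g, index=idx, columns=[f"rs{j}" for j in range(k)])
    return G, pd.Series(x, index=idx), pd.Series(y, index=idx)


class TestTwoStageLeastSquares:
    def test_single_instrument_equals_wald_ratio(self):
        import statsmodels.api as sm
        G, x, y = _confounded(k=1)
        est = two_stage_least_squares(G, x, y, "linear")
        bzx = sm.OLS(x, sm.add_constant(G["rs0"])).fit().params.iloc[1]
        bzy = sm.OLS(y, sm.add_constant(G["rs0"])).fit().params.iloc[1]
        assert est.effect == pytest.approx(bzy / bzx, abs=1e-8)

    def test_recovers_causal_effect_where_ols_is_biased(self):
        import statsmodels.api as sm
        errs, naive_biases = [], []
        for seed in range(5):
            G, x, y = _confounded(seed=seed)
            est = two_stage_least_squares(G, x, y, "linear")
            errs.append(abs(est.effect - 0.5))
            naive = sm.OLS(y.to_numpy(),
                           sm.add_constant(x.to_numpy())).fit().params[1]
            naive_biases.append(abs(naive - 0.5))
        assert np.mean(errs) < 0.05
        assert min(naive_biases) > 0.2  # designed confounding bias ~ 0.3

    def test_multi_instrument_is_strength_weighted_ratio_average(self):
        import statsmodels.api as sm
        G, x, y = _confounded(k=3)
        est = two_stage_least_squares(G, x, y, "linear")
        # equivalent closed form: beta_2SLS = cov(xhat, y) / var(xhat)
        xhat = sm.OLS(x, sm.add_constant(G)).fit().fittedvalues
        ref = np.cov(xhat, y)[0, 1] / np.var(xhat, ddof=1)
        assert est.effect == pytest.approx(ref, rel=1e-10)

    def test_null_instrument_ci_covers_null(self):
        G, x, _ = _confounded(k=2, seed=3)
        rng = np.random.default_rng(9)
        y_indep = pd.Series(rng.standard_normal(len(x)), index=x.index)
        est = two_stage_least_squares(G, x, y_indep, "linear")
        assert est.ci_low < 0.0 < est.ci_high

    def test_allele_flip_invariance(self):
        G, x, y = _confounded(k=2, seed=4)
        est_a = two_stage_least_squares(G, x, y, "linear")
        est_b = two_stage_least_squares(2.0 - G, x, y, "linear")
        assert est_a.effect == pytest.approx(est_b.effect, rel=1e-10)

    def test_survival_outcome_returns_hr(self):
        rng = np.random.default_rng(5)
        n = 2000
        g = rng.binomial(2, 0.3, (n, 2)).astype(float)
        x = g @ np.array([0.4, 0.4]) + rng.standard_normal(n)
        T = 8.0 * (-np.log(rng.uniform(size=n)) / np.exp(0.5 * x)) ** (1 / 1.2)
        C = rng.uniform(0.5, 10, n)
        idx = pd.Index([f"S{i}" for i in range(n)])
        G = pd.DataFrame(g, index=idx, columns=["rs1", "rs2"])
        oc = surv_frame(np.minimum(T, C), (T <= C).astype(int), index=idx)
        est = two_stage_least_squares(G, pd.Series(x, index=idx), oc,
                                      "survival")
        assert est.outcome_type == "survival"
        assert est.ci_low < np.exp(0.5) < est.ci_high

    def test_weak_instrument_warns(self):
        rng = np.random.default_rng(6)
        n = 300
        G = pd.DataFrame({"rs1": rng.binomial(2, 0.3, n).astype(float)})
        x = pd.Series(rng.standard_normal(n))
        y = pd.Series(rng.standard_normal(n))
        with pytest.warns(UserWarning, match="weak instrument"):
            two_stage_least_squares(G, x, y, "linear")

    def test_collinear_instrument_dropped(self):
        G, x, y = _confounded(k=2, seed=7)
        G = G.copy()
        G["rs_dup"] = G["rs0"] * 2.0
        with pytest.warns(UserWarning, match="collinear"):
            est = two_stage_least_squares(G, x, y, "linear")
        assert est.n_instruments == 2


def test_vcf_reader_roundtrip(tmp_path):
    pytest.importorskip("cyvcf2")
    from metabosurv.mr import read_genotypes_vcf
    vcf = tmp_path / "g.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "1\t100\trsA\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t200\trsB\tC\tT\t.\tPASS\t.\tGT\t0/1\t./.\t0/0\n")
    g, snp_map = read_genotypes_vcf(vcf)
    assert list(g.index) == ["S1", "S2", "S3"]
    np.testing.assert_array_equal(g["rsA"], [0.0, 1.0, 2.0])
    assert np.isnan(g.loc["S2", "rsB"])
    assert snp_map.set_index("snp").loc["rsB", "pos_bp"] == 200
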