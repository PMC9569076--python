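"""Prognostic model building, scoring, and evaluation metric oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabosurv import (
    RiskModel,
    reclassification_metrics,
    risk_at_horizon,
    risk_score,
    stepwise_aic_cox,
    stratify_and_logrank,
    time_dependent_auc,
    youden_cutoff,
)

from conftest import simulate_survival, surv_frame


def _model(coefs: dict, endpoint="death") -> RiskModel:
    s = pd.Series(coefs, dtype=float)
    return RiskModel(variables=list(s.index), coefficients=s,
                     endpoint=endpoint, aic=np.nan,
                     wald_p=pd.Series(0.0, index=s.index))


class TestStepwise:
    def test_strong_candidate_retained(self):
        X, oc = simulate_survival(600, [np.log(2.0)] + [0.0] * 5, seed=20,
                                  scale=6.0)
        mdl = stepwise_aic_cox(X, list(X.columns), oc)
        assert "m000" in mdl.variables
        assert (mdl.wald_p < 0.1).all()

    def test_null_candidates_give_sparse_model_and_minimal_aic(self):
        X, oc = simulate_survival(400, [0.0] * 6, seed=21, scale=6.0)
        mdl = stepwise_aic_cox(X, list(X.columns), oc)
        from metabosurv.model import _fit_aic
        full_aic, _ = _fit_aic(X, tuple(X.columns), oc)
        assert mdl.aic <= full_aic + 1e-9
        assert len(mdl.variables) <= 2

    def test_deterministic_given_candidate_order(self):
        X, oc = simulate_survival(400, [0.6, 0.4, 0.0, 0.0], seed=22,
                                  scale=6.0)
        a = stepwise_aic_cox(X, list(X.columns), oc)
        b = stepwise_aic_cox(X, list(X.columns)[::-1], oc)
        assert a.variables == b.variables  # internal sort fixes the path

    def test_warns_on_many_candidates(self):
        X, oc = simulate_survival(100, [0.0] * 8, seed=23, scale=50.0)
        if oc["event"].sum() >= 10:
            with pytest.warns(UserWarning, match="events per variable"):
                stepwise_aic_cox(X, list(X.columns), oc)


class TestRiskScore:
    def test_zero_coefficients_give_unit_score(self):
        X = pd.DataFrame({"a": [1.0, -2.0, 3.0]})
        mdl = _model({"a": 0.0})
        assert (risk_score(mdl, X) == 1.0).all()

    def test_hand_computed_exponential(self):
        mdl = _model({"a": 0.22})
        X = pd.DataFrame({"a": [1.0]})
        assert risk_score(mdl, X).iloc[0] == pytest.approx(np.exp(0.22))
        assert np.exp(0.22) == pytest.approx(1.246, abs=5e-4)

    def test_monotone_in_positive_coefficient(self):
        mdl = _model({"a": 0.5})
        X = pd.DataFrame({"a": [1.0, 2.0]})
        s = risk_score(mdl, X)
        assert s.iloc[1] > s.iloc[0]

    def test_missing_variable_named(self):
        mdl = _model({"a": 0.5, "zzz": 0.1})
        with pytest.raises(KeyError, match="zzz"):
            risk_score(mdl, pd.DataFrame({"a": [1.0]}))

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-2, 2), min_size=2, max_size=5))
    def test_invariant_to_variable_order(self, coefs):
        names = [f"v{i}" for i in range(len(coefs))]
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((8, len(names))), columns=names)
        a = risk_score(_model(dict(zip(names, coefs))), X)
        rev = dict(zip(reversed(names), reversed(coefs)))
        b = risk_score(_model(rev), X[list(reversed(names))])
        np.testing.assert_allclose(a, b, rtol=1e-12)


class TestTimeDependentAuc:
    def test_constant_score_is_chance(self):
        oc = surv_frame([1, 2, 3, 4, 5, 6], [1, 0, 1, 0, 1, 0])
        s = pd.Series(2.0, index=oc.index)
        assert time_dependent_auc(s, oc, 3.5) == pytest.approx(50.0)

    def test_perfect_separation_is_100(self):
        # all events score above all non-events, no censoring before t
        oc = surv_frame([1, 2, 2.5, 8, 9, 10, 11, 12],
                        [1, 1, 1, 0, 0, 0, 0, 0])
        s = pd.Series([10.0, 9.0, 8.0, 1.0, 2.0, 0.5, 1.5, 0.2],
                      index=oc.index)
        assert time_dependent_auc(s, oc, 5.0) == pytest.approx(100.0)

    def test_invariant_to_monotone_transform(self):
        X, oc = simulate_survival(300, [0.8], seed=24)
        s = pd.Series(X["m000"].to_numpy(), index=oc.index)
        a = time_dependent_auc(s, oc, 4.0)
        b = time_dependent_auc(np.exp(s / 3.0), oc, 4.0)
        assert a == pytest.approx(b, abs=1e-9)

    def test_increases_with_effect_size(self):
        aucs = []
        for beta in (0.2, 0.8, 1.6):
            X, oc = simulate_survival(800, [beta], seed=25)
            aucs.append(time_dependent_auc(X["m000"], oc, 4.0))
        assert aucs[0] < aucs[1] < aucs[2]

    def test_no_events_before_horizon_rejected(self):
        oc = surv_frame([5, 6, 7, 8], [1, 1, 0, 0])
        with pytest.raises(ValueError, match="no events"):
            time_dependent_auc(pd.Series([1, 2, 3, 4.0], index=oc.index),
                               oc, 1.0)


class TestReclassification:
    @staticmethod
    def _risks(n=300, seed=26):
        X, oc = simulate_survival(n, [1.0, 0.0], seed=seed, scale=6.0)
        mdl_new = stepwise_aic_cox(X, ["m000"], oc)
        risk_new = risk_at_horizon(mdl_new, X, 3.0)
        rng = np.random.default_rng(seed)
        risk_ref = pd.Series(rng.uniform(0.05, 0.5, n), index=X.index)
        return risk_new, risk_ref, oc

    def test_identical_models_give_exact_zero(self):
        risk_new, _, oc = self._risks()
        cmp_ = reclassification_metrics(risk_new, risk_new.copy(), oc, 3.0,
                                        n_boot=20, seed=0)
        assert cmp_.idi == 0.0 and cmp_.nri == 0.0

    def test_idi_equals_brute_force_slope_difference(self):
        risk_new, risk_ref, oc = self._risks()
        cmp_ = reclassification_metrics(risk_new, risk_ref, oc, 3.0,
                                        n_boot=20, seed=0)
        # independent direct-definition computation, plain loops
        ev, nev, dn, dr = [], [], [], []
        for sid in oc.index:
            t, e = oc.loc[sid, "time"], oc.loc[sid, "event"]
            if e == 1 and t <= 3.0:
                ev.append(sid)
            elif t > 3.0:
                nev.append(sid)
        slope_new = (np.mean([risk_new[s] for s in ev])
                     - np.mean([risk_new[s] for s in nev]))
        slope_ref = (np.mean([risk_ref[s] for s in ev])
                     - np.mean([risk_ref[s] for s in nev]))
        assert cmp_.idi == pytest.approx(slope_new - slope_ref, abs=1e-12)

    def test_nri_matches_direct_definition(self):
        risk_new, risk_ref, oc = self._risks()
        cmp_ = reclassification_metrics(risk_new, risk_ref, oc, 3.0,
                                        n_boot=20, seed=0)
        ev, nev = [], []
        for sid in oc.index:
            t, e = oc.loc[sid, "time"], oc.loc[sid, "event"]
            if e == 1 and t <= 3.0:
                ev.append(sid)
            elif t > 3.0:
                nev.append(sid)
        p_up_e = np.mean([risk_new[s] > risk_ref[s] for s in ev])
        p_dn_e = np.mean([risk_new[s] < risk_ref[s] for s in ev])
        p_up_n = np.mean([risk_new[s] > risk_ref[s] for s in nev])
        p_dn_n = np.mean([risk_new[s] < risk_ref[s] for s in nev])
        assert cmp_.nri == pytest.approx(
            p_up_e - p_dn_e + p_dn_n - p_up_n, abs=1e-12)

    def test_true_predictor_yields_positive_idi(self):
        pos = 0
        for seed in range(10):
            X, oc = simulate_survival(500, [np.log(2.0)], seed=40 + seed,
                                      scale=6.0)
            mdl = stepwise_aic_cox(X, ["m000"], oc)
            if not mdl.variables:
                continue
            rn = risk_at_horizon(mdl, X, 3.0)
            rr = pd.Series(np.full(len(X), float(rn.mean())), index=X.index)
            c = reclassification_metrics(rn, rr, oc, 3.0, n_boot=10, seed=0)
            pos += c.idi > 0
        assert pos >= 9

    def test_bootstrap_reproducible(self):
        risk_new, risk_ref, oc = self._risks()
        a = reclassification_metrics(risk_new, risk_ref, oc, 3.0,
                                     n_boot=50, seed=7)
        b = reclassification_metrics(risk_new, risk_ref, oc, 3.0,
                                     n_boot=50, seed=7)
        assert a.idi_ci == b.idi_ci and a.nri_ci == b.nri_ci


class TestYouden:
    def test_perfect_separation(self):
        s = pd.Series([1, 2, 3, 10, 11, 12.0])
        y = pd.Series([0, 0, 0, 1, 1, 1])
        res = youden_cutoff(s, y)
        assert res["youden_j"] == pytest.approx(1.0)
        assert 3 < res["cutoff"] <= 10

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(27)
        s = pd.Series(rng.normal(size=200))
        y = pd.Series((rng.uniform(size=200) < 0.4).astype(int))
        res = youden_cutoff(s, y)
        best_j, best_c = -np.inf, None
        for c in sorted(s.unique()):
            sens = ((s >= c) & (y == 1)).sum() / (y == 1).sum()
            spec = ((s < c) & (y == 0)).sum() / (y == 0).sum()
            j = sens + spec - 1
            if j > best_j + 1e-12:
                best_j, best_c = j, c
        assert res["cutoff"] == pytest.approx(best_c)
        assert res["youden_j"] == pytest.approx(best_j)

    def test_tie_break_smallest_cutoff(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0])
        y = pd.Series([0, 1, 0, 1])
        res = youden_cutoff(s, y)  # J ties at several thresholds
        candidates = []
        for c in sorted(s.unique()):
            sens = ((s >= c) & (y == 1)).sum() / 2
            spec = ((s < c) & (y == 0)).sum() / 2
            candidates.append((c, sens + spec - 1))
        jmax = max(j for _, j in candidates)
        smallest = min(c for c, j in candidates if j == pytest.approx(jmax))
        assert res["cutoff"] == smallest

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            youden_cutoff(pd.Series([1, 2.0]), pd.Series([1, 1]))


class TestStratification:
    def test_quartile_partition_sizes(self):
        X, oc = simulate_survival(400, [0.5], seed=28)
        strat = stratify_and_logrank(pd.Series(np.exp(X["m000"]),
                                               index=oc.index), oc)
        sizes = strat.groups.value_counts()
        assert sizes["low"] == pytest.approx(100, abs=2)
        assert sizes["middle"] == pytest.approx(200, abs=3)
        assert sizes["high"] == pytest.approx(100, abs=2)
        assert set(strat.km_curves) == {"low", "middle", "high"}

    def test_separated_groups_significant(self):
        X, oc = simulate_survival(500, [1.2], seed=29, scale=6.0)
        strat = stratify_and_logrank(pd.Series(np.exp(X["m000"]),
                                               index=oc.index), oc)
        assert strat.logrank_p < 0.01

    def test_constant_scores_rejected(self):
        X, oc = simulate_survival(50, [0.5], seed=30)
        with pytest.raises(ValueError, match="identical"):
            stratify_and_logrank(pd.Series(1.0, index=oc.index), oc)

    def test_small_n_rejected(self):
        X, oc = simulate_survival(10, [0.5], seed=31)
        with pytest.raises(ValueError, match="n >= 12"):
            stratify_and_logrank(pd.Series(X["m000"], index=oc.index), oc)
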