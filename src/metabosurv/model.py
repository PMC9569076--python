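"""Multivariable prognostic Cox models and their evaluation.

Builds the four model families compared in the analysis (clinical-only,
reference-biomarker + clinical, metabolomic, metabolomic + clinical) with a
bidirectional AIC stepwise search and a Wald-P retention pass; scores
patients with h(X) = exp(sum beta_i x_i); and evaluates models by
time-dependent (cumulative/dynamic, IPCW) AUC, integrated discrimination
improvement (IDI), continuous net reclassification improvement (NRI),
Youden-index cutoffs, and quartile risk stratification with the log-rank
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

__all__ = [
    "RiskModel", "ModelComparison", "RiskStratification",
    "stepwise_aic_cox", "risk_score", "risk_at_horizon",
    "time_dependent_auc", "reclassification_metrics", "youden_cutoff",
    "stratify_and_logrank",
]


@dataclass
class RiskModel:
    """A fitted multivariable Cox model: variables, coefficients, AIC and
    per-variable Wald P, plus the fitter itself for baseline-hazard use."""

    variables: list
    coefficients: pd.Series
    endpoint: str
    aic: float
    wald_p: pd.Series
    fitter: CoxPHFitter | None = None

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "aic": self.aic,
            "coefficients": {v: float(self.coefficients[v]) for v in self.variables},
            "wald_p": {v: float(self.wald_p[v]) for v in self.variables},
        }


@dataclass
class ModelComparison:
    auc_new: float               # percent
    auc_ref: float               # percent
    idi: float
    idi_ci: tuple
    nri: float
    nri_ci: tuple
    n_boot: int


@dataclass
class RiskStratification:
    scores: pd.Series
    groups: pd.Series            # low / middle / high
    q1: float
    q3: float
    logrank_stat: float
    logrank_p: float
    km_curves: dict = field(default_factory=dict)


def _null_loglik(time: np.ndarray, event: np.ndarray) -> float:
    from .select import breslow_loglik
    return breslow_loglik(np.zeros((len(time), 1)), time, event, np.zeros(1))


def _fit_aic(data: pd.DataFrame, variables: tuple, outcome: pd.DataFrame
             ) -> tuple[float, CoxPHFitter | None]:
    if not variables:
        ll0 = _null_loglik(outcome["time"].to_numpy(), outcome["event"].to_numpy())
        return -2.0 * ll0, None
    df = data[list(variables)].join(outcome[["time", "event"]])
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    return float(cph.AIC_partial_), cph


def stepwise_aic_cox(data: pd.DataFrame, candidates: list,
                     outcome: pd.DataFrame, retention_p: float = 0.1,
                     endpoint: str = "death") -> RiskModel:
    """Bidirectional stepwise Cox search minimizing the partial-likelihood
    AIC, followed by a retention pass that iteratively drops variables with
    Wald P >= ``retention_p``.

    Candidate order is fixed (sorted by name) so the search path — hence the
    result — is deterministic. Starts from the empty model. If no variable
    survives, an empty model is returned with a warning (clinical-only
    fallback is the caller's concern).
    """
    candidates = sorted(candidates)
    n_events = int(outcome["event"].sum())
    if n_events < 5 * len(candidates):
        warnings.warn(
            f"{n_events} events for {len(candidates)} candidates: fewer than "
            "5 events per variable, estimates may be unstable")
    cache: dict = {}

    def aic_of(vs: tuple) -> float:
        key = frozenset(vs)
        if key not in cache:
            cache[key] = _fit_aic(data, vs, outcome)
        return cache[key][0]

    current: tuple = ()
    current_aic = aic_of(current)
    while True:
        moves = []
        for v in candidates:
            if v not in current:
                moves.append(current + (v,))
        for v in current:
            moves.append(tuple(x for x in current if x != v))
        best, best_aic = None, current_aic
        for mv in moves:
            a = aic_of(mv)
            if a < best_aic - 1e-9:
                best, best_aic = mv, a
        if best is None:
            break
        current, current_aic = best, best_aic

    # retention pass: drop worst Wald P >= threshold, refit, repeat
    while current:
        _, cph = cache[frozenset(current)]
        p = cph.summary["p"].reindex(list(current))
        worst = p.idxmax()
        if p[worst] < retention_p:
            break
        current = tuple(v for v in current if v != worst)
        aic_of(current)

    if not current:
        warnings.warn("stepwise search retained no variable")
        return RiskModel(variables=[], coefficients=pd.Series(dtype=float),
                         endpoint=endpoint, aic=aic_of(()), wald_p=pd.Series(dtype=float))
    aic, cph = cache[frozenset(current)]
    ordered = [v for v in sorted(current)]
    return RiskModel(
        variables=ordered,
        coefficients=cph.params_.reindex(ordered),
        endpoint=endpoint, aic=aic,
        wald_p=cph.summary["p"].reindex(ordered),
        fitter=cph,
    )


def risk_score(model: RiskModel, X: pd.DataFrame) -> pd.Series:
    """Per-sample hazard estimate h(X) = exp(sum beta_i * x_i)."""
    missing = [v for v in model.variables if v not in X.columns]
    if missing:
        raise KeyError(f"model variable(s) missing from data: {missing}")
    if not model.variables:
        return pd.Series(1.0, index=X.index, name="risk_score")
    lin = X[model.variables].to_numpy(float) @ model.coefficients.to_numpy(float)
    return pd.Series(np.exp(lin), index=X.index, name="risk_score")


def risk_at_horizon(model: RiskModel, X: pd.DataFrame, t: float) -> pd.Series:
    """Absolute risk 1 - S(t | X) from the model's Breslow baseline."""
    if model.fitter is None:
        raise ValueError("model has no fitted baseline (empty model)")
    surv = model.fitter.predict_survival_function(X[model.variables], times=[t])
    return 1.0 - surv.iloc[0].rename("risk")


def time_dependent_auc(scores: pd.Series, outcome: pd.DataFrame, t: float
                       ) -> float:
    """Cumulative/dynamic AUC at horizon ``t`` with IPCW weighting (Uno),
    returned in percent. Requires at least one event at or before ``t`` and
    one sample still at risk after ``t``."""
    time = outcome["time"].to_numpy(float)
    event = outcome["event"].to_numpy(bool)
    if not np.any(event & (time <= t)):
        raise ValueError(f"no events observed before horizon t={t}")
    if not np.any(time > t):
        raise ValueError(f"no samples at risk beyond horizon t={t}")
    y = Surv.from_arrays(event, time)
    s = np.asarray(scores.loc[outcome.index], float)
    if np.ptp(s) == 0:
        return 50.0  # uninformative score: chance discrimination
    auc, _ = cumulative_dynamic_auc(y, y, s, times=[t])
    return float(auc[0]) * 100.0


def _status_at(outcome: pd.DataFrame, t: float) -> pd.Series:
    """1 = event by t, 0 = event-free beyond t, NaN = censored before t."""
    time, event = outcome["time"], outcome["event"].astype(bool)
    status = pd.Series(np.nan, index=outcome.index)
    status[event & (time <= t)] = 1.0
    status[time > t] = 0.0
    return status


def reclassification_metrics(risk_new: pd.Series, risk_ref: pd.Series,
                             outcome: pd.DataFrame, t: float,
                             n_boot: int = 1000, seed: int = 0) -> ModelComparison:
    """IDI and continuous NRI of a new risk model against a reference.

    ``risk_new`` / ``risk_ref`` are absolute risks at ``t`` (1 - S(t|X) from
    each model). Event status is assessed at ``t``; samples censored before
    ``t`` are excluded. IDI is the difference in discrimination slopes:
    (mean risk_new - mean risk_ref | events) - (same | non-events).
    Continuous NRI is P(up|event) - P(down|event) + P(down|non-event) -
    P(up|non-event). CIs are percentile bootstrap over samples with the
    stated replicate count.
    """
    status = _status_at(outcome, t).dropna()
    rn = risk_new.loc[status.index].to_numpy(float)
    rr = risk_ref.loc[status.index].to_numpy(float)
    ev = status.to_numpy() == 1.0
    if ev.sum() == 0 or (~ev).sum() == 0:
        raise ValueError("need both events and non-events at the horizon")

    def _idi(rn, rr, ev):
        d = rn - rr
        return d[ev].mean() - d[~ev].mean()

    def _nri(rn, rr, ev):
        up, down = rn > rr, rn < rr
        return (up[ev].mean() - down[ev].mean()
                + down[~ev].mean() - up[~ev].mean())

    idi, nri = _idi(rn, rr, ev), _nri(rn, rr, ev)
    rng = np.random.default_rng(seed)
    bi, bn = np.empty(n_boot), np.empty(n_boot)
    n = len(ev)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        e = ev[idx]
        if e.sum() == 0 or (~e).sum() == 0:
            bi[b], bn[b] = np.nan, np.nan
            continue
        bi[b] = _idi(rn[idx], rr[idx], e)
        bn[b] = _nri(rn[idx], rr[idx], e)
    auc_new = time_dependent_auc(risk_new, outcome, t)
    auc_ref = time_dependent_auc(risk_ref, outcome, t)
    return ModelComparison(
        auc_new=auc_new, auc_ref=auc_ref,
        idi=idi, idi_ci=(float(np.nanpercentile(bi, 2.5)),
                         float(np.nanpercentile(bi, 97.5))),
        nri=nri, nri_ci=(float(np.nanpercentile(bn, 2.5)),
                         float(np.nanpercentile(bn, 97.5))),
        n_boot=n_boot,
    )


def youden_cutoff(scores: pd.Series, y: pd.Series) -> dict:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1 over all
    observed score values (classification rule: score >= cutoff is
    positive). Ties in J resolve to the smallest qualifying cutoff."""
    s = np.asarray(scores, float)
    yy = np.asarray(y, int)
    if yy.min() == yy.max():
        raise ValueError("need both classes to compute a cutoff")
    best = None
    for c in np.unique(s):
        pred = s >= c
        sens = (pred & (yy == 1)).sum() / (yy == 1).sum()
        spec = (~pred & (yy == 0)).sum() / (yy == 0).sum()
        j = sens + spec - 1.0
        if best is None or j > best["youden_j"] + 1e-12:
            best = {"cutoff": float(c), "sensitivity": float(sens),
                    "specificity": float(spec), "youden_j": float(j)}
    return best


def stratify_and_logrank(scores: pd.Series, outcome: pd.DataFrame
                         ) -> RiskStratification:
    """Quartile risk groups — low (< Q1), middle (Q1..Q3 inclusive), high
    (> Q3) — compared by the 3-group log-rank test, with per-group
    Kaplan-Meier curves."""
    if len(scores) < 12:
        raise ValueError("need n >= 12 for non-degenerate quartiles")
    s = scores.loc[outcome.index]
    if np.ptp(s.to_numpy(float)) == 0:
        raise ValueError("all risk scores identical: cannot stratify")
    q1, q3 = s.quantile(0.25), s.quantile(0.75)
    groups = pd.Series("middle", index=s.index)
    groups[s < q1] = "low"
    groups[s > q3] = "high"
    res = multivariate_logrank_test(outcome["time"], groups, outcome["event"])
    curves = {}
    for g, idx in groups.groupby(groups).groups.items():
        km = KaplanMeierFitter()
        km.fit(outcome.loc[idx, "time"], outcome.loc[idx, "event"], label=str(g))
        curves[g] = km.survival_function_
    return RiskStratification(
        scores=s, groups=groups, q1=float(q1), q3=float(q3),
        logrank_stat=float(res.test_statistic), logrank_p=float(res.p_value),
        km_curves=curves,
    )
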