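"""Four-model mediation decomposition with proportion mediated.

Quantifies how much of a metabolite's association with a dichotomous outcome
(death or MACE by end of follow-up) is carried through a continuous mediator
(LVEF):

    model 1:  Y = c X            (total effect)
    model 2:  M = b1 X           (exposure -> mediator)
    model 3:  Y = b2 M           (mediator -> outcome)
    model 4:  Y = b2' M + c' X   (direct effect c')

indirect = b1 * b2' and proportion mediated = (b1 * b2') / c, with
percentile-bootstrap confidence intervals. For the dichotomous outcome the
Y-models use a probit (latent-scale) link by default, matching the
categorical-endogenous convention of structural-equation software; a linear
(-probability) link is available and makes the closed-form additivity
c = c' + b1*b2 exact in the Gaussian limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["MediationResult", "mediate", "mediation_screen"]


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    c_total: float
    beta1: float                 # X -> M
    beta2: float                 # M -> Y (from the joint model 4)
    beta2_marginal: float        # M -> Y slope of model 3 (Y on M alone)
    c_direct: float
    indirect: float              # beta1 * beta2
    proportion: float            # indirect / total; NaN if |c| < tol
    p_total: float
    p_mediated: float
    ci: dict = field(default_factory=dict)
    n: int = 0
    n_boot: int = 0
    reported: bool = True        # dual-significance rule


def _fit_y(y: np.ndarray, design: np.ndarray, link: str):
    X = sm.add_constant(design)
    if link == "probit":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.Probit(y, X).fit(disp=0)
    return sm.OLS(y, X).fit()


def _decompose(x, m, y, cov, link) -> tuple[float, float, float, float, float]:
    """(c, b1, b2_marginal, b2, c') from the four regressions. The product
    of coefficients uses b2 from the joint model (Y on M + X); the marginal
    model-3 slope is reported for completeness."""
    def D(*parts):
        cols = [p.reshape(-1, 1) for p in parts]
        if cov is not None:
            cols.append(cov)
        return np.hstack(cols)

    c = _fit_y(y, D(x), link).params[1]
    b1 = sm.OLS(m, sm.add_constant(D(x))).fit().params[1]
    b2_marg = _fit_y(y, D(m), link).params[1]
    m4 = _fit_y(y, D(m, x), link).params
    b2, c_dir = m4[1], m4[2]
    return float(c), float(b1), float(b2_marg), float(b2), float(c_dir)


def mediate(X: pd.Series, M: pd.Series, Y: pd.Series,
            covariates: pd.DataFrame | None = None,
            link: str = "probit", n_boot: int = 1000, seed: int = 0,
            c_tol: float = 1e-8,
            exposure_name: str | None = None, mediator_name: str = "lvef",
            outcome_name: str = "outcome") -> MediationResult:
    """Product-of-coefficients mediation of X on Y through M.

    ``link`` governs the Y-models: "probit" for a dichotomous Y (default) or
    "linear" (OLS; required when Y is continuous, and the basis of the
    closed-form checks). Complete cases only (listwise deletion). When the
    total effect is numerically zero (|c| < ``c_tol``) the proportion is
    undefined and returned as NaN with ``reported=False``.
    """
    if link not in ("probit", "linear"):
        raise ValueError("link must be 'probit' or 'linear'")
    df = pd.DataFrame({"x": X, "m": M, "y": Y})
    if covariates is not None:
        df = df.join(covariates)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        warnings.warn(f"listwise deletion removed {n0 - len(df)} incomplete rows")
    x = df["x"].to_numpy(float)
    m = df["m"].to_numpy(float)
    y = df["y"].to_numpy(float)
    if link == "probit":
        uy = np.unique(y)
        if not np.isin(uy, [0.0, 1.0]).all() or len(uy) < 2:
            raise ValueError("probit link requires a binary outcome with "
                             "both classes present")
    cov = df.drop(columns=["x", "m", "y"]).to_numpy(float) \
        if covariates is not None else None

    c, b1, b2_marg, b2, c_dir = _decompose(x, m, y, cov, link)
    indirect = b1 * b2
    prop = indirect / c if abs(c) >= c_tol else np.nan
    p_total = float(_fit_y(y, np.hstack(
        [x.reshape(-1, 1)] + ([cov] if cov is not None else [])), link).pvalues[1])

    rng = np.random.default_rng(seed)
    draws = {"c": [], "b1": [], "b2": [], "c_dir": [], "indirect": [], "prop": []}
    for _ in range(n_boot):
        bi = rng.integers(0, len(x), len(x))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cb, b1b, _, b2b, cdb = _decompose(
                    x[bi], m[bi], y[bi], None if cov is None else cov[bi], link)
        except Exception:
            continue
        ib = b1b * b2b
        draws["c"].append(cb); draws["b1"].append(b1b); draws["b2"].append(b2b)
        draws["c_dir"].append(cdb); draws["indirect"].append(ib)
        draws["prop"].append(ib / cb if abs(cb) >= c_tol else np.nan)
    ci = {}
    for k, v in draws.items():
        v = np.asarray(v, float)
        ci[k] = (float(np.nanpercentile(v, 2.5)), float(np.nanpercentile(v, 97.5))) \
            if len(v) else (np.nan, np.nan)
    ind = np.asarray(draws["indirect"], float)
    if len(ind):
        # two-sided bootstrap P for the mediated (indirect) effect
        frac = min((ind <= 0).mean(), (ind >= 0).mean())
        p_med = float(min(1.0, 2.0 * frac))
        p_med = max(p_med, 2.0 / (len(ind) + 1))  # resolution floor
    else:
        p_med = np.nan
    return MediationResult(
        exposure=exposure_name or (X.name or "x"), mediator=mediator_name,
        outcome=outcome_name, c_total=c, beta1=b1, beta2=b2,
        beta2_marginal=b2_marg, c_direct=c_dir,
        indirect=indirect, proportion=float(prop), p_total=p_total,
        p_mediated=p_med, ci=ci, n=len(x), n_boot=n_boot,
        reported=not np.isnan(prop),
    )


def mediation_screen(metabolites: list, X: pd.DataFrame, M: pd.Series,
                     outcomes: dict, covariates: pd.DataFrame | None = None,
                     link: str = "probit", n_boot: int = 1000, seed: int = 0,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Mediation decomposition for each (metabolite, endpoint) pair.

    ``metabolites`` should be the MR-supported LVEF hits; ``outcomes`` maps
    endpoint name -> binary event-by-end-of-follow-up Series. A result is
    flagged ``reported`` only when both the total and the mediated effect
    are significant at ``alpha`` (the dual-significance rule).
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    for i, met in enumerate(metabolites):
        for j, (endpoint, y) in enumerate(sorted(outcomes.items())):
            sub_seed = int(np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=(i, j)).generate_state(1)[0] % (2**31))
            res = mediate(X[met], M, y, covariates=covariates, link=link,
                          n_boot=n_boot, seed=sub_seed, exposure_name=met,
                          outcome_name=endpoint)
            passed = (res.p_total < alpha) and (res.p_mediated < alpha) \
                and res.reported
            rows.append({
                "metabolite": met, "endpoint": endpoint,
                "proportion_pct": 100.0 * res.proportion,
                "c_total": res.c_total, "beta1": res.beta1,
                "beta2": res.beta2, "c_direct": res.c_direct,
                "p_total": res.p_total, "p_mediated": res.p_mediated,
                "reported": passed,
            })
    return pd.DataFrame(rows)
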