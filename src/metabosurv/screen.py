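"""Per-metabolite association screening with confounder adjustment and FDR.

Each metabolite is tested one at a time: Cox proportional hazards against a
survival endpoint (death or MACE), or ordinary least squares against a
continuous remodeling trait (LVEF or LVMI), optionally adjusting for the
17-covariate confounder table. Hazard ratios are reported per 1 SD of the
metabolite; Benjamini-Hochberg adjustment is applied across metabolites
within each (model, endpoint) family.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from statsmodels.stats.multitest import multipletests

__all__ = ["cox_screen", "linear_screen", "bh_fdr", "standardize"]


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Scale each column to unit SD (and zero mean) so effects are per-SD."""
    sd = X.std(ddof=1).replace(0.0, 1.0)
    return (X - X.mean()) / sd


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the number of tests m and propagated as
    NaN in the output.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _univariate_cox_batch(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                          max_iter: int = 50, tol: float = 1e-9
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Newton-Raphson univariate Cox fits for every column of X at once
    (Efron tie handling). Returns (beta, se) per column.

    This is the screening fast path: fitting hundreds of single-covariate
    models through a general solver dominates screen runtime, while the
    one-dimensional Newton update vectorizes across metabolites. Adjusted
    fits (with confounders) go through lifelines.
    """
    from scipy.stats import norm  # noqa: F401  (callers use norm for p)

    order = np.argsort(time, kind="stable")
    X = X[order]
    time = time[order]
    event = event[order].astype(bool)
    n, m = X.shape
    # tied-event groups: indices of first member of each distinct event time
    ev_idx = np.flatnonzero(event)
    if len(ev_idx) == 0:
        return np.zeros(m), np.full(m, np.inf)
    ev_times = time[ev_idx]
    grp_start = np.r_[0, 1 + np.flatnonzero(np.diff(ev_times) > 0)]
    grp_sizes = np.diff(np.r_[grp_start, len(ev_idx)])
    # risk set of a group = all samples with time >= group time
    risk_start = np.searchsorted(time, ev_times[grp_start], side="left")
    xe_sum = np.add.reduceat(X[ev_idx], grp_start, axis=0)

    beta = np.zeros(m)
    for _ in range(max_iter):
        eta = X * beta  # (n, m)
        np.clip(eta, -200, 200, out=eta)
        w = np.exp(eta)
        wx = w * X
        wxx = wx * X
        # suffix sums: S_k[i] = sum_{j >= i}
        s0 = np.cumsum(w[::-1], axis=0)[::-1]
        s1 = np.cumsum(wx[::-1], axis=0)[::-1]
        s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
        grad = xe_sum.sum(axis=0).astype(float)
        hess = np.zeros(m)
        for g, (st, d) in enumerate(zip(grp_start, grp_sizes)):
            r = risk_start[g]
            members = ev_idx[st:st + d]
            S0, S1, S2 = s0[r], s1[r], s2[r]
            if d == 1:
                denom = S0
                grad -= S1 / denom
                hess -= S2 / denom - (S1 / denom) ** 2
            else:
                T0 = w[members].sum(axis=0)
                T1 = wx[members].sum(axis=0)
                T2 = wxx[members].sum(axis=0)
                for loc in range(d):
                    f = loc / d
                    denom = S0 - f * T0
                    num1 = S1 - f * T1
                    num2 = S2 - f * T2
                    grad -= num1 / denom
                    hess -= num2 / denom - (num1 / denom) ** 2
        step = grad / np.where(hess == 0, -1.0, hess)
        beta_new = beta - step
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    # information at the optimum for Wald SEs
    se = np.sqrt(1.0 / np.maximum(-hess, 1e-300))
    return beta, se


def _design(met: pd.Series, confounders: pd.DataFrame | None) -> pd.DataFrame:
    cols = {"metabolite": met}
    df = pd.DataFrame(cols, index=met.index)
    if confounders is not None:
        df = df.join(confounders)
    return df


def _drop_aliased(X: pd.DataFrame) -> pd.DataFrame:
    """Drop trailing collinear columns until the design has full rank."""
    while X.shape[1] > 1:
        arr = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
        rank = np.linalg.matrix_rank(arr)
        if rank == arr.shape[1]:
            return X
        # find the last column that is linearly dependent on its predecessors
        for j in range(X.shape[1], 0, -1):
            sub = np.column_stack([np.ones(len(X)), X.iloc[:, :j].to_numpy(float)])
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                dropped = X.columns[j - 1]
                warnings.warn(f"dropping aliased covariate {dropped!r}")
                X = X.drop(columns=[dropped])
                break
    return X


def cox_screen(matrix: pd.DataFrame, outcome: pd.DataFrame,
               confounders: pd.DataFrame | None = None,
               already_standardized: bool = False) -> pd.DataFrame:
    """One Cox PH fit per metabolite (Efron ties, Wald inference).

    Parameters
    ----------
    matrix : study-samples x metabolites (Pareto-scaled or raw; columns are
        re-standardized to unit SD unless ``already_standardized``).
    outcome : DataFrame with columns ``time`` and ``event`` on the same index.
    confounders : optional confounder table for the adjusted analysis.

    Returns one row per metabolite: hr (per 1 SD), ci_low, ci_high, p, fdr,
    converged. Non-converged fits carry NaN and are excluded from the FDR
    family.
    """
    if outcome["event"].sum() < 10:
        warnings.warn("fewer than 10 events: screen estimates will be unstable")
    X = matrix if already_standardized else standardize(matrix)
    X = X.loc[outcome.index]
    if confounders is None and not X.isna().any().any():
        # univariate screen: vectorized Newton solver across metabolites
        from scipy.stats import norm

        beta, se = _univariate_cox_batch(
            X.to_numpy(float), outcome["time"].to_numpy(float),
            outcome["event"].to_numpy(int))
        z = norm.ppf(0.975)
        res = pd.DataFrame({
            "metabolite": X.columns,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - z * se),
            "ci_high": np.exp(beta + z * se),
            "p": 2.0 * norm.sf(np.abs(beta / se)),
            "converged": True,
        })
        res["fdr"] = bh_fdr(res["p"])
        return res
    rows = []
    for met in X.columns:
        df = _design(X[met], confounders).join(outcome[["time", "event"]])
        df = df.dropna()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(df, duration_col="time", event_col="event")
            s = cph.summary.loc["metabolite"]
            rows.append((met, s["exp(coef)"], s["exp(coef) lower 95%"],
                         s["exp(coef) upper 95%"], s["p"], True))
        except (ConvergenceError, ValueError, np.linalg.LinAlgError) as e:
            warnings.warn(f"Cox fit failed for {met}: {e}")
            rows.append((met, np.nan, np.nan, np.nan, np.nan, False))
    res = pd.DataFrame(rows, columns=["metabolite", "hr", "ci_low", "ci_high",
                                      "p", "converged"])
    res["fdr"] = bh_fdr(res["p"])
    return res


def linear_screen(matrix: pd.DataFrame, trait: pd.Series,
                  confounders: pd.DataFrame | None = None,
                  already_standardized: bool = False) -> pd.DataFrame:
    """One OLS fit per metabolite against a continuous trait (LVEF or LVMI).

    Effects are per 1 SD of the metabolite, reported as estimate +/- SE with
    Wald CI and BH-FDR across metabolites. Aliased confounders are dropped
    with a warning.
    """
    import statsmodels.api as sm

    trait = trait.dropna()
    if len(trait) < 0.8 * len(matrix):
        warnings.warn("trait observed for < 80% of samples")
    X = matrix if already_standardized else standardize(matrix)
    X = X.loc[trait.index]
    conf = None
    if confounders is not None:
        conf = _drop_aliased(confounders.loc[trait.index])
    rows = []
    for met in X.columns:
        design = _design(X[met], conf)
        fit = sm.OLS(trait.to_numpy(float),
                     sm.add_constant(design.to_numpy(float))).fit()
        est, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
        ci = fit.conf_int()[1]
        rows.append((met, est, se, ci[0], ci[1], p))
    res = pd.DataFrame(rows, columns=["metabolite", "estimate", "se",
                                      "ci_low", "ci_high", "p"])
    res["fdr"] = bh_fdr(res["p"])
    return res
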