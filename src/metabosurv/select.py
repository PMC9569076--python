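"""Stability selection of metabolic signatures by repeated CV LASSO-Cox.

The screening survivors (adjusted FDR < 0.05) enter an L1-penalized Cox model
in which the clinical confounders are unpenalized adjustment terms (penalty
factor 0). For each of R repeats the cross-validation folds are reshuffled,
the penalty is chosen by held-out partial-likelihood deviance, the model is
refit on the full data at that penalty, and the nonzero candidate
coefficients are recorded. The output mirrors the field's frequency-table
layout: averaged coefficient beta, HR = exp(beta), and selection frequency
out of R.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = ["breslow_loglik", "stability_lasso_cox", "select_signatures"]


def breslow_loglik(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                   beta: np.ndarray) -> float:
    """Cox partial log-likelihood with Breslow tie handling (used as the
    held-out deviance criterion; ties in CV folds are rare and Breslow keeps
    the criterion cheap)."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # descending time
    eta, time, event = eta[order], time[order], event[order]
    # cumulative log-sum-exp of risk set (all j with t_j >= t_i)
    m = eta.max() if len(eta) else 0.0
    cum = np.logaddexp.accumulate(eta - m) + m
    # risk set for sample i (descending order): samples 0..i, but ties in time
    # must share the same risk set -> index of last sample with equal time
    last_eq = np.searchsorted(-time, -time, side="right") - 1
    ll = float(np.sum(event * (eta - cum[last_eq])))
    return ll


def _cv_deviance(X: np.ndarray, y, alphas: np.ndarray, penalty_factor: np.ndarray,
                 folds: int, rng: np.random.Generator) -> np.ndarray:
    """Mean held-out deviance (-2 * test partial log-likelihood) per alpha."""
    event = y["event"].astype(int)
    time = y["time"]
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31 - 1)))
    dev = np.zeros((folds, len(alphas)))
    for f, (tr, te) in enumerate(skf.split(X, event)):
        fit = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, alphas=alphas, penalty_factor=penalty_factor,
            fit_baseline_model=False)
        fit.fit(X[tr], Surv.from_arrays(event[tr].astype(bool), time[tr]))
        fitted_alphas = list(fit.alphas_)
        for a_i, a in enumerate(alphas):
            if a in fitted_alphas:
                beta = fit.coef_[:, fitted_alphas.index(a)]
            else:  # path terminated early; reuse the closest smaller alpha
                beta = fit.coef_[:, -1]
            dev[f, a_i] = -2.0 * breslow_loglik(X[te], time[te], event[te], beta)
    return dev.mean(axis=0)


def stability_lasso_cox(candidates: pd.DataFrame, outcome: pd.DataFrame,
                        confounders: pd.DataFrame | None = None,
                        folds: int = 10, repeats: int = 200, seed: int = 0,
                        penalty: str = "min", average: str = "all",
                        n_alphas: int = 30) -> pd.DataFrame:
    """Repeated cross-validated LASSO-Cox with selection-frequency counting.

    Parameters
    ----------
    candidates : study-samples x candidate-metabolites matrix (SD units).
    outcome : columns ``time``, ``event`` on the same index.
    confounders : unpenalized adjustment covariates (penalty factor 0).
    penalty : "min" (deviance-minimizing alpha, default) or "1se".
    average : "all" (mean beta over all repeats, zeros included — this is
        what reproduces small coefficients at low frequency) or "nonzero".

    Returns a frame with metabolite, coefficient, hr, frequency, sorted by
    descending frequency. Deterministic for a fixed seed.
    """
    if penalty not in ("min", "1se"):
        raise ValueError("penalty must be 'min' or '1se'")
    if average not in ("all", "nonzero"):
        raise ValueError("average must be 'all' or 'nonzero'")
    if outcome["event"].sum() < folds:
        raise ValueError("need at least one event per fold")
    cand_cols = list(candidates.columns)
    X_df = candidates.loc[outcome.index]
    if confounders is not None:
        X_df = X_df.join(confounders.loc[outcome.index])
    X = X_df.to_numpy(float)
    pf = np.r_[np.ones(len(cand_cols)),
               np.zeros(X.shape[1] - len(cand_cols))]
    y = {"time": outcome["time"].to_numpy(float),
         "event": outcome["event"].to_numpy(float)}
    y_surv = Surv.from_arrays(y["event"].astype(bool), y["time"])

    # one alpha grid for all repeats, from the full-data path
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path = CoxnetSurvivalAnalysis(
            l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.01,
            penalty_factor=pf)
        path.fit(X, y_surv)
    alphas = np.asarray(path.alphas_)

    coefs = np.zeros((repeats, len(cand_cols)))
    nonzero = np.zeros((repeats, len(cand_cols)), dtype=bool)
    failures = 0
    ss = np.random.SeedSequence(seed)
    for r in range(repeats):
        for attempt in range(10):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=ss.entropy,
                                       spawn_key=(r, attempt)))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    dev = _cv_deviance(X, y, alphas, pf, folds, rng)
                    if penalty == "min":
                        a_star = alphas[int(np.argmin(dev))]
                    else:  # 1se: largest alpha within 1 SE of the minimum
                        se = dev.std(ddof=1) / np.sqrt(len(dev))
                        ok = dev <= dev.min() + se
                        a_star = alphas[np.flatnonzero(ok)[0]]
                    refit = CoxnetSurvivalAnalysis(
                        l1_ratio=1.0, alphas=[a_star], penalty_factor=pf)
                    refit.fit(X, y_surv)
                break
            except (ArithmeticError, ValueError) as e:  # pragma: no cover
                failures += 1
                warnings.warn(f"repeat {r} attempt {attempt} failed ({e}); redrawing")
        else:  # pragma: no cover
            raise RuntimeError(f"repeat {r}: 10 consecutive failures")
        if failures > 0.05 * repeats + 1:
            raise RuntimeError(
                f"{failures} repeat-level failures exceed the 5% tolerance")
        b = refit.coef_[: len(cand_cols), 0]
        coefs[r] = b
        nonzero[r] = b != 0

    freq = nonzero.sum(axis=0)
    if average == "all":
        mean_b = coefs.mean(axis=0)
    else:
        with np.errstate(invalid="ignore"):
            mean_b = np.where(freq > 0, coefs.sum(axis=0) / np.maximum(freq, 1), 0.0)
    out = pd.DataFrame({
        "metabolite": cand_cols,
        "coefficient": mean_b,
        "hr": np.exp(mean_b),
        "frequency": freq,
    })
    return out.sort_values(["frequency", "metabolite"],
                           ascending=[False, True]).reset_index(drop=True)


def select_signatures(selection: pd.DataFrame, min_frequency: int = 1) -> list:
    """Candidates selected in at least ``min_frequency`` repeats, in
    descending-frequency order. Variables never selected (frequency 0) are
    removed; an empty result is allowed (downstream models fall back to
    clinical covariates only, with a warning)."""
    if selection.empty:
        raise ValueError("empty selection table")
    kept = selection.loc[selection["frequency"] >= min_frequency]
    if kept.empty:
        warnings.warn("no candidate reached the frequency threshold; "
                      "downstream model will be clinical-only")
    return kept["metabolite"].tolist()
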