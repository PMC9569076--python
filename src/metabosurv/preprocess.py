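"""Metabolomics preprocessing: feature QC, LOD imputation, QC-RLSC, Pareto.

The pipeline order is fixed and enforced by :func:`preprocess_pipeline`:

1. drop features whose coefficient of variation across pooled-QC injections
   exceeds 50% (CV on raw intensities, sd/mean);
2. replace below-LOD missing values by the feature's minimum observed value;
3. QC-RLSC — per analytical block (batch) and feature, fit a robust local
   quadratic (LOESS) regression of QC intensity on injection order, divide
   every injection by the drift curve interpolated at its order, and rescale
   by the feature's overall QC median so block-level offsets are removed;
4. Pareto scaling per block: (x - mean) / sqrt(sd).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import MetaboMatrix

__all__ = [
    "FeatureQC",
    "NormalizedMatrix",
    "qc_cv",
    "filter_by_qc_cv",
    "impute_lod",
    "loess_fit",
    "qc_rlsc",
    "pareto_scale",
    "preprocess_pipeline",
]


@dataclass
class NormalizedMatrix:
    """Pareto-scaled intensities with the per-(block, feature) centering and
    scaling constants used."""

    values: pd.DataFrame
    blocks: pd.Series            # block id per sample
    means: pd.DataFrame          # block x feature
    sds: pd.DataFrame            # block x feature (sd before scaling)


def qc_cv(matrix: MetaboMatrix) -> pd.Series:
    """Per-feature coefficient of variation (sd/mean, ddof=1) over QC rows,
    on raw intensities. Missing values are ignored."""
    qc = matrix.qc()
    if qc.shape[0] == 0:
        raise ValueError(
            "no QC samples found: supply is_qc flags in the sample table")
    return qc.std(ddof=1) / qc.mean()


def filter_by_qc_cv(matrix: MetaboMatrix, threshold: float = 0.5
                    ) -> tuple[pd.DataFrame, MetaboMatrix]:
    """Drop features with QC CV strictly above ``threshold``.

    Returns the per-feature QC report (metabolite, qc_cv, kept) and the
    filtered matrix. A feature at exactly the threshold is kept (the removal
    rule is CV > 50%, strict).
    """
    qc = matrix.qc()
    if qc.shape[0] < 3:
        raise ValueError(f"need >= 3 QC samples to estimate CV, found {qc.shape[0]}")
    cv = qc_cv(matrix)
    kept = ~(cv > threshold)  # NaN CV (all-missing QC) is dropped too
    kept &= cv.notna()
    report = pd.DataFrame({"metabolite": cv.index, "qc_cv": cv.to_numpy(),
                           "kept": kept.to_numpy()}).reset_index(drop=True)
    filtered = MetaboMatrix(
        intensities=matrix.intensities.loc[:, kept[kept].index],
        samples=matrix.samples,
    )
    return report, filtered


def impute_lod(matrix: MetaboMatrix) -> MetaboMatrix:
    """Assign each missing (below-LOD) value the minimum observed value of
    its metabolite — the minimum detection level."""
    intens = matrix.intensities
    all_missing = intens.columns[intens.isna().all()]
    if len(all_missing):
        raise ValueError(
            f"cannot impute all-missing metabolite(s): {list(all_missing)}")
    return MetaboMatrix(intensities=intens.fillna(intens.min()),
                        samples=matrix.samples)


def loess_fit(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
              span: float = 0.75, degree: int = 2, robust_iter: int = 2
              ) -> np.ndarray:
    """Robust locally weighted polynomial regression (LOESS).

    Tricube neighbourhood weights over the ``span`` fraction of nearest
    points, local polynomial of ``degree``, and ``robust_iter`` bisquare
    re-weighting passes to resist outlying QC injections. Evaluation points
    outside [min(x), max(x)] take the fit at the nearest boundary.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)
    order = np.argsort(x)
    x, y = x[order], y[order]
    rw = np.ones(n)  # robustness weights
    x_eval = np.asarray(x_eval, float)
    x_clip = np.clip(x_eval, x[0], x[-1])

    def _fit_at(x0: float, rw: np.ndarray) -> float:
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        dk = d[idx].max()
        if dk == 0:
            return float(np.average(y[idx], weights=rw[idx])) \
                if rw[idx].sum() > 0 else float(y[idx].mean())
        w = (1 - (d[idx] / dk) ** 3) ** 3
        w = np.clip(w, 0, None) * rw[idx]
        if w.sum() == 0:
            w = np.ones_like(w)
        deg = min(degree, len(idx) - 1)
        xs = x[idx] - x0  # center for conditioning
        X = np.vander(xs, deg + 1, increasing=True)
        W = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * W[:, None], y[idx] * W, rcond=None)
        return float(coef[0])

    for it in range(robust_iter + 1):
        fitted = np.array([_fit_at(xi, rw) for xi in x])
        if it == robust_iter:
            break
        resid = y - fitted
        s = np.median(np.abs(resid))
        if s == 0:
            break
        u = resid / (6.0 * s)
        rw = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
    return np.array([_fit_at(xe, rw) for xe in x_clip])


def qc_rlsc(matrix: MetaboMatrix, span: float = 0.75, min_qc: int = 5
            ) -> tuple[MetaboMatrix, dict]:
    """Quality Control-Robust LOESS Signal Correction.

    Per analytical block and feature, the drift curve is the robust LOESS fit
    of QC intensity against injection order; every injection in the block is
    divided by the curve at its own order, then multiplied by the feature's
    QC median across all blocks, removing both within-block drift and
    between-block offsets. Blocks with fewer than ``min_qc`` QC injections
    for a feature fall back to a constant correction by the block QC median
    (with a warning).

    Returns the corrected matrix and a dict of per-(block, feature) fitted
    drift curves indexed by injection order.

    Raises if any fitted drift value is non-positive (degenerate fit), naming
    the feature and sample.
    """
    samples = matrix.samples.set_index("sample_id")
    intens = matrix.intensities
    if intens.isna().any().any():
        raise ValueError("qc_rlsc requires an imputed (complete) matrix")
    corrected = intens.copy()
    drift_curves: dict = {}
    # floor for negative corrected values: the feature's minimum raw value
    lod_floor = intens.min()
    global_qc_median = intens.loc[samples["is_qc"].reindex(intens.index)].median()

    for block, block_samples in samples.groupby("batch"):
        rows = block_samples.index
        order = block_samples["injection_order"]
        qc_rows = block_samples.index[block_samples["is_qc"]]
        x_qc = order.loc[qc_rows].to_numpy(float)
        x_all = order.to_numpy(float)
        for feat in intens.columns:
            y_qc = intens.loc[qc_rows, feat].to_numpy(float)
            if len(qc_rows) < min_qc:
                warnings.warn(
                    f"block {block}, {feat}: only {len(qc_rows)} QC points; "
                    "using constant block-median correction")
                fit = np.full(x_all.size, np.median(y_qc))
            else:
                fit = loess_fit(x_qc, y_qc, x_all, span=span)
            if np.any(fit <= 0):
                bad = rows[np.flatnonzero(fit <= 0)[0]]
                raise ValueError(
                    f"degenerate drift fit (<= 0) for {feat} at sample {bad}")
            corrected.loc[rows, feat] = (
                intens.loc[rows, feat].to_numpy() / fit * global_qc_median[feat])
            drift_curves[(block, feat)] = pd.Series(fit, index=x_all)
    neg = corrected < 0
    if neg.any().any():
        warnings.warn("negative corrected intensities floored at feature LOD")
        corrected = corrected.mask(neg, lod_floor, axis=1)
    return MetaboMatrix(intensities=corrected, samples=matrix.samples), drift_curves


def pareto_scale(matrix: MetaboMatrix, drop_qc: bool = True) -> NormalizedMatrix:
    """Pareto scaling per analytical block: x' = (x - mean) / sqrt(sd).

    Constant features within a block are centered only (a warning is
    emitted). QC rows are excluded from the output by default — the scaled
    matrix feeds the statistical models, which see study samples only — but
    scaling constants are computed from the same rows that are returned.
    """
    samples = matrix.samples.set_index("sample_id")
    intens = matrix.intensities
    if drop_qc:
        keep = ~samples["is_qc"].reindex(intens.index).to_numpy()
        intens = intens.loc[keep]
    blocks = samples["batch"].reindex(intens.index)
    out = intens.copy().astype(float)
    means, sds = {}, {}
    warned = False
    for block, rows in intens.groupby(blocks.to_numpy()).groups.items():
        sub = intens.loc[rows]
        mu = sub.mean()
        sd = sub.std(ddof=1).fillna(0.0)
        const = sd == 0
        if const.any() and not warned:
            warnings.warn("constant feature(s) centered without scaling")
            warned = True
        denom = np.sqrt(sd.where(~const, 1.0))
        out.loc[rows] = (sub - mu) / denom
        means[block], sds[block] = mu, sd
    return NormalizedMatrix(values=out, blocks=blocks,
                            means=pd.DataFrame(means).T, sds=pd.DataFrame(sds).T)


def preprocess_pipeline(matrix: MetaboMatrix, cv_threshold: float = 0.5,
                        span: float = 0.75) -> tuple[NormalizedMatrix, pd.DataFrame]:
    """CV filter -> LOD imputation -> QC-RLSC -> Pareto scaling, in that
    order. Returns the normalized study-sample matrix and a QC report with
    per-feature CV before and after drift correction."""
    report, filtered = filter_by_qc_cv(matrix, threshold=cv_threshold)
    imputed = impute_lod(filtered)
    corrected, _ = qc_rlsc(imputed, span=span)
    cv_after = qc_cv(corrected)
    report = report.merge(
        cv_after.rename("qc_cv_after"), left_on="metabolite", right_index=True,
        how="left")
    report = report.rename(columns={"qc_cv": "qc_cv_before"})
    normalized = pareto_scale(corrected)
    return normalized, report[["metabolite", "qc_cv_before", "qc_cv_after", "kept"]]
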