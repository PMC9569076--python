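import warnings

import numpy as np
import pandas as pd
import pytest

from metabosurv import CohortConfig, MetaboMatrix, simulate_cohort


def make_matrix(columns: dict, n_qc: int = 3, n_study: int = 3,
                batch: int = 1) -> MetaboMatrix:
    """Hand-built MetaboMatrix: the first n_qc rows of each column are QC
    injections, the rest study samples."""
    n = n_qc + n_study
    ids = [f"QC{i}" for i in range(n_qc)] + [f"S{i}" for i in range(n_study)]
    intens = pd.DataFrame(columns, index=pd.Index(ids, name="sample_id"))
    samples = pd.DataFrame({
        "sample_id": ids,
        "batch": batch,
        "injection_order": np.arange(1, n + 1),
        "is_qc": [True] * n_qc + [False] * n_study,
    })
    return MetaboMatrix(intensities=intens, samples=samples)


def surv_frame(time, event, index=None) -> pd.DataFrame:
    idx = index if index is not None else pd.RangeIndex(len(time))
    return pd.DataFrame({"time": np.asarray(time, float),
                         "event": np.asarray(event, int)}, index=idx)


def simulate_survival(n, beta, seed=0, shape=1.2, scale=8.0, cmax=10.0):
    """Direct Weibull-PH draw: X ~ N(0,1)^p, eta = X @ beta, uniform + admin
    censoring. Returns (X DataFrame, outcome DataFrame)."""
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta, float)
    X = rng.standard_normal((n, len(beta)))
    eta = X @ beta
    T = scale * (-np.log(rng.uniform(size=n)) / np.exp(eta)) ** (1 / shape)
    C = rng.uniform(0.5, cmax, n)
    idx = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    Xdf = pd.DataFrame(X, index=idx,
                       columns=[f"m{j:03d}" for j in range(len(beta))])
    oc = surv_frame(np.minimum(T, C), (T <= C).astype(int), index=idx)
    return Xdf, oc


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by integration-style tests."""
    cfg = CohortConfig(
        n_samples=300, n_metabolites=30, n_batches=2, qc_every=10,
        n_snps=8, seed=42,
        hazard_effects={"met_0001": {"death": float(np.log(2.0)),
                                     "mace": float(np.log(1.8))},
                        "met_0002": {"death": float(np.log(1.6)),
                                     "mace": float(np.log(1.6))}},
        mediator_effects={"met_0001": -2.0},
        instrument_effects={"met_0001": (["rs0001", "rs0002"], 0.35)},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(cfg)
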