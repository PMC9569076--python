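"""Spearman correlation network between outcome-associated metabolites and
clinical factors.

All pairwise Spearman correlations are computed; an edge is retained when
P < 0.01 and |rho| exceeds a class-specific threshold: 0.1 when the pair
involves a clinical factor, 0.2 for metabolite-metabolite pairs. The edge
list exports to TSV and GraphML for desktop graph viewers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["build_network", "to_graphml"]


def _spearman(x: np.ndarray, y: np.ndarray, n_exact: int = 20) -> tuple[float, float]:
    """Spearman rho and two-sided P; exact permutation P for small n, else
    the large-sample t approximation (tie-corrected, scipy)."""
    if len(x) < n_exact:
        res = stats.spearmanr(x, y)
        perm = stats.permutation_test(
            (x,), lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings", n_resamples=9999,
            random_state=np.random.default_rng(0))
        return float(res.statistic), float(perm.pvalue)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def build_network(metabolites: pd.DataFrame, clinical_factors: pd.DataFrame,
                  rho_clinical: float = 0.1, rho_metab: float = 0.2,
                  p_max: float = 0.01, min_obs: int = 10,
                  mixed_threshold: str = "clinical") -> pd.DataFrame:
    """Pairwise Spearman edge list over metabolites and clinical factors.

    Edge kept iff p < ``p_max`` and |rho| > the class threshold: clinical
    threshold when either endpoint is clinical (``mixed_threshold`` may be
    set to "metabolite" to use the stricter rule for mixed pairs), metabolite
    threshold otherwise. Self-loops excluded; pairs with fewer than
    ``min_obs`` complete observations or a constant member are skipped with
    a warning.
    """
    nodes = pd.concat([metabolites, clinical_factors], axis=1)
    classes = {c: "metabolite" for c in metabolites.columns}
    classes.update({c: "clinical" for c in clinical_factors.columns})
    cols = list(nodes.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = nodes[[a, b]].dropna()
            if len(sub) < min_obs:
                warnings.warn(f"{a} ~ {b}: fewer than {min_obs} complete "
                              "observations; skipped")
                continue
            xa, xb = sub[a].to_numpy(float), sub[b].to_numpy(float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                warnings.warn(f"{a} ~ {b}: constant variable; skipped")
                continue
            rho, p = _spearman(xa, xb)
            n_clin = (classes[a] == "clinical") + (classes[b] == "clinical")
            if n_clin == 2:
                thr = rho_clinical
            elif n_clin == 0:
                thr = rho_metab
            else:
                thr = rho_clinical if mixed_threshold == "clinical" else rho_metab
            if p < p_max and abs(rho) > thr:
                rows.append((a, b, classes[a], classes[b], rho, p))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "class_a",
                                       "class_b", "rho", "p"])


def to_graphml(edges: pd.DataFrame, path) -> None:
    """Write the edge list as GraphML (undirected, rho/p edge attributes,
    node class attribute) for import into desktop graph tools."""
    import networkx as nx

    g = nx.Graph()
    for _, e in edges.iterrows():
        g.add_node(e["node_a"], node_class=e["class_a"])
        g.add_node(e["node_b"], node_class=e["class_b"])
        g.add_edge(e["node_a"], e["node_b"], rho=float(e["rho"]), p=float(e["p"]))
    nx.write_graphml(g, path)
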