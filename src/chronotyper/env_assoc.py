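"""Chronotype medoids and their environmental correlation profiles.

Each chronotype is represented by its medoid — the member series minimizing
the total Euclidean distance to all other members.  Medoid series are
Spearman-correlated with every environmental parameter over the observed
(non-interpolated) months; p-values are Holm-adjusted within each medoid's
family of parameter tests.  The medoid-by-parameter rho matrix is then
clustered hierarchically to reveal groups of chronotypes that respond to the
environment in the same way (e.g. temperature-positive versus
nutrient-positive clades).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .core_data import AbundanceMatrix, EnvMatrix

__all__ = [
    "MedoidCorrelation",
    "find_medoid",
    "chronotype_medoids",
    "correlate_medoids",
    "cluster_correlation_profiles",
]


@dataclass
class MedoidCorrelation:
    chronotype: int
    medoid_votu_id: str
    rho: dict[str, float]
    p_raw: dict[str, float]
    p_adj: dict[str, float]
    significant: dict[str, bool]


def find_medoid(X: np.ndarray, member_ids) -> str:
    """Member minimizing the sum of Euclidean distances to all others; ties
    broken by the lexicographically smallest id."""
    ids = [str(i) for i in member_ids]
    if len(ids) == 0:
        raise ValueError("empty chronotype")
    if len(ids) == 1:
        return ids[0]
    sums = squareform(pdist(np.asarray(X, dtype=float))).sum(axis=1)
    return min(zip(sums, ids))[1]


def chronotype_medoids(matrix_values: np.ndarray, votu_ids,
                       memberships: dict[str, int]) -> dict[int, str]:
    """Medoid vOTU of every chronotype, from z-scored series."""
    ids = [str(i) for i in votu_ids]
    index = {v: i for i, v in enumerate(ids)}
    out = {}
    for c in sorted(set(memberships.values())):
        members = sorted(v for v, cc in memberships.items() if cc == c)
        out[c] = find_medoid(matrix_values[[index[v] for v in members]], members)
    return out


def correlate_medoids(matrix: AbundanceMatrix, medoids: dict[int, str],
                      env: EnvMatrix, alpha: float = 0.05,
                      adjust: str = "holm") -> pd.DataFrame:
    """Spearman correlation of each chronotype medoid series with each
    environmental parameter, restricted to observed (non-interpolated)
    months shared by both tables.

    ``adjust`` "holm" applies Holm's step-down within each medoid's family of
    parameter tests; "none" reports raw p in p_adj (the raw reading of the
    significance colouring).  Returns a long-format table.
    """
    obs = matrix.original_timepoints()
    am_months = matrix.month_index[obs]
    shared = sorted(set(am_months) & set(env.month_index))
    if len(shared) < 4:
        raise ValueError("need >= 4 shared observed timepoints")
    am_cols = [int(np.where(matrix.month_index == m)[0][0]) for m in shared]
    env_cols = [int(np.where(env.month_index == m)[0][0]) for m in shared]
    rows = []
    for c in sorted(medoids):
        vid = medoids[c]
        series = matrix.row(vid)[am_cols]
        rhos, ps = [], []
        for pi, param in enumerate(env.parameters):
            rho, p = spearmanr(series, env.raw[pi, env_cols])
            rhos.append(float(rho))
            ps.append(float(p))
        if adjust == "holm":
            p_adj = multipletests(ps, method="holm")[1]
        elif adjust == "none":
            p_adj = np.array(ps)
        else:
            raise ValueError(f"unknown adjust {adjust!r}")
        for param, rho, p, pa in zip(env.parameters, rhos, ps, p_adj):
            rows.append((c, vid, param, rho, p, float(pa), bool(pa < alpha)))
    return pd.DataFrame(rows, columns=["chronotype", "medoid", "parameter",
                                       "rho", "p", "p_adj", "significant"])


def cluster_correlation_profiles(corr: pd.DataFrame, n_groups: int = 2,
                                 method: str = "complete"):
    """Hierarchical clustering (Euclidean, complete linkage) of medoid rho
    profiles.  Returns (linkage matrix, {chronotype: group}, rho matrix)."""
    rho = corr.pivot(index="chronotype", columns="parameter", values="rho")
    if rho.shape[0] < 2:
        raise ValueError("need >= 2 medoids to cluster")
    Z = linkage(pdist(rho.to_numpy()), method=method)
    labels = fcluster(Z, t=n_groups, criterion="maxclust")
    return Z, dict(zip(rho.index.astype(int), (int(l) for l in labels))), rho
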