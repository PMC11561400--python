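"""ChronoClustR: bootstrap consensus clustering of abundance time series into
chronotypes.

A chronotype is a cluster of series with similar temporal abundance patterns,
optimally separated from the other clusters.  One bootstrap round works on
z-scored series and proceeds:

1. randomly partition the series into subgroups (default 100 members);
2. cluster each subgroup hierarchically on Euclidean distances and keep the
   cut with the best mean silhouette; collect its cluster-mean centroids;
3. K-means over the pooled centroids for every k = 1..n_centroids-1, record
   the within-cluster sum of squares (WSS) curve, and pick k by the
   tangent-line elbow rule;
4. cluster the *full* collection at that k and record which pairs of series
   land in the same cluster.

Co-membership counts over all rounds form the consensus co-occurrence matrix;
average-linkage agglomeration of (1 - co-occurrence) gives the consensus
dendrogram, which is cut into max(per-round k) chronotypes, so the final
partition honours the finest granularity any round supported.

The per-round partition randomness is keyed to the sorted series identifiers,
so permuting input row order permutes all outputs consistently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "SubgroupClustering",
    "ChronotypeModel",
    "partition_subgroups",
    "cluster_subgroup",
    "elbow_k",
    "kmeans_centroid_meta",
    "cluster_collection",
    "bootstrap_consensus",
    "export_dendrogram",
]


@dataclass
class SubgroupClustering:
    member_ids: list[str]
    labels: np.ndarray
    k_opt: int
    silhouette: float
    centroids: np.ndarray  # k_opt x T cluster-mean series


@dataclass
class ChronotypeModel:
    votu_ids: list[str]              # sorted
    cooccurrence: np.ndarray
    per_bootstrap_k: list[int]
    k_final: int
    linkage_matrix: np.ndarray       # consensus dendrogram (scipy linkage)
    memberships: dict[str, int]
    seed: int
    n_bootstraps: int

    def membership_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"votu_id": self.votu_ids,
                             "chronotype": [self.memberships[v] for v in self.votu_ids]})


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def partition_subgroups(ids, subgroup_size: int = 100,
                        rng: np.random.Generator | None = None,
                        min_remainder: int = 10) -> list[list[str]]:
    """Random permutation of ids chunked into blocks of ``subgroup_size``; a
    trailing remainder smaller than ``min_remainder`` is merged into the
    previous block.  The permutation is drawn over the sorted ids, so the
    result does not depend on input order."""
    ids = sorted(str(i) for i in ids)
    if len(ids) < min_remainder:
        raise ValueError(f"need at least {min_remainder} ids")
    rng = np.random.default_rng() if rng is None else rng
    perm = [ids[i] for i in rng.permutation(len(ids))]
    blocks = [perm[i:i + subgroup_size] for i in range(0, len(perm), subgroup_size)]
    if len(blocks) > 1 and len(blocks[-1]) < min_remainder:
        blocks[-2].extend(blocks.pop())
    return blocks


def cluster_subgroup(X: np.ndarray, member_ids, k_max: int = 20,
                     method: str = "complete") -> SubgroupClustering:
    """Hierarchical clustering of one subgroup on Euclidean distances; the
    returned cut maximizes the mean silhouette over k = 2..min(k_max, n-1).

    Identical series (zero distances throughout) are degenerate: a single
    cluster is returned with a warning.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("subgroup clustering requires >= 3 series")
    dist = pdist(X)
    if not np.any(dist > 0):
        warnings.warn("all series identical in subgroup; returning one cluster")
        return SubgroupClustering(list(member_ids), np.zeros(n, int), 1, float("nan"),
                                  X.mean(axis=0, keepdims=True))
    Z = linkage(dist, method=method)
    sq = squareform(dist)
    best = None
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(sq, labels, metric="precomputed")
        if best is None or s > best[0]:
            best = (s, k, labels)
    s, k, labels = best
    centroids = np.vstack([X[labels == c].mean(axis=0) for c in np.unique(labels)])
    return SubgroupClustering(list(member_ids), labels, int(len(np.unique(labels))),
                              float(s), centroids)


def elbow_k(wss) -> int:
    """Elbow of a WSS-versus-k curve by the tangent-line rule: the smallest k
    whose drop to k+1 first falls to or below the mean absolute slope of the
    whole curve.  The curve is forced non-increasing first.  Falls back to
    k = 2 when no drop qualifies."""
    wss = np.minimum.accumulate(np.asarray(wss, dtype=float))
    K = wss.size
    if K < 3:
        raise ValueError("elbow rule requires WSS for k = 1..K with K >= 3")
    drops = -np.diff(wss)          # drops[k-1] = WSS(k) - WSS(k+1)
    mean_slope = drops.mean()
    for k in range(2, K):          # candidate k in [2, K-1]
        if drops[k - 1] <= mean_slope:
            return k
    return 2


def kmeans_centroid_meta(centroids: np.ndarray,
                         rng: np.random.Generator | None = None,
                         n_init: int = 10) -> tuple[np.ndarray, int]:
    """K-means over pooled subgroup centroids for every k = 1..n-1; returns
    the WSS curve and the elbow-rule optimum."""
    C = np.asarray(centroids, dtype=float)
    n = C.shape[0]
    if n < 4:
        raise ValueError("centroid meta-clustering requires >= 4 centroids")
    rng = np.random.default_rng() if rng is None else rng
    wss = []
    for k in range(1, n):
        km = KMeans(n_clusters=k, n_init=n_init,
                    random_state=int(rng.integers(2 ** 31 - 1)))
        km.fit(C)
        wss.append(km.inertia_)
    wss = np.array(wss)
    return wss, elbow_k(wss)


def cluster_collection(X: np.ndarray, k: int, method: str = "tsclust",
                       linkage_method: str = "ward") -> np.ndarray:
    """Cluster the full series collection into k groups.

    method "tsclust" (default) is agglomerative clustering on Euclidean
    distances between the z-scored series with ``linkage_method`` (default
    Ward's minimum-variance criterion, which recovers planted compact phase
    groups far more reliably than complete or average linkage on this kind
    of data); "hierarchical" uses average linkage; "kmeans" runs K-means.
    Returns integer labels 1..k.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValueError("k cannot exceed the number of series")
    if k == n:
        return np.arange(1, n + 1)
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(X)
        return km.labels_ + 1
    if method == "hierarchical":
        linkage_method = "average"
    elif method != "tsclust":
        raise ValueError(f"unknown method {method!r}")
    Z = linkage(pdist(X), method=linkage_method)
    return fcluster(Z, t=k, criterion="maxclust")


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def bootstrap_consensus(values: np.ndarray, votu_ids, n_bootstraps: int = 100,
                        subgroup_size: int = 100, seed: int = 0,
                        k_max_subgroup: int = 20, method: str = "tsclust",
                        collection_linkage: str = "ward",
                        consensus_linkage: str = "average") -> ChronotypeModel:
    """Run the full bootstrap consensus pipeline on z-scored series.

    Each round draws a fresh random subgroup partition (the bootstrap unit is
    the partition-dependent pipeline, not a with-replacement resample, so the
    full-collection co-occurrence accounting stays exact) and contributes one
    co-membership matrix; see the module docstring for the steps.
    """
    if n_bootstraps < 2:
        raise ValueError("need >= 2 bootstrap rounds")
    ids = [str(i) for i in votu_ids]
    order = np.argsort(np.array(ids))
    sorted_ids = [ids[i] for i in order]
    X = np.asarray(values, dtype=float)[order]
    n = X.shape[0]
    index = {v: i for i, v in enumerate(sorted_ids)}
    co = np.zeros((n, n))
    per_k: list[int] = []
    for b in range(n_bootstraps):
        rng = np.random.default_rng([seed, b])
        blocks = partition_subgroups(sorted_ids, subgroup_size, rng)
        cents = []
        for block in blocks:
            sub = cluster_subgroup(X[[index[v] for v in block]], block,
                                   k_max=k_max_subgroup)
            cents.append(sub.centroids)
        cents = np.vstack(cents)
        if cents.shape[0] >= 4:
            _, k_b = kmeans_centroid_meta(cents, rng)
        else:
            k_b = max(2, cents.shape[0])
        k_b = min(k_b, n)
        per_k.append(int(k_b))
        labels = cluster_collection(X, k_b, method=method,
                                    linkage_method=collection_linkage)
        co += labels[:, None] == labels[None, :]
    co /= n_bootstraps
    np.fill_diagonal(co, 1.0)
    k_final = int(max(per_k))
    Z = linkage(squareform(1.0 - co, checks=False), method=consensus_linkage)
    memberships = fcluster(Z, t=k_final, criterion="maxclust")
    return ChronotypeModel(sorted_ids, co, per_k, k_final, Z,
                           {v: int(c) for v, c in zip(sorted_ids, memberships)},
                           int(seed), int(n_bootstraps))


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _newick(node.left, labels)
    right = _newick(node.right, labels)
    bl_l = node.dist - node.left.dist
    bl_r = node.dist - node.right.dist
    return f"({left}:{bl_l:.10g},{right}:{bl_r:.10g})"


def export_dendrogram(model: ChronotypeModel, path) -> None:
    """Write the consensus dendrogram as Newick (leaf names = vOTU ids,
    branch lengths = merge-height differences)."""
    if model.linkage_matrix is None:
        raise ValueError("model has no fitted dendrogram")
    tree = to_tree(model.linkage_matrix)
    with open(path, "w") as fh:
        fh.write(_newick(tree, model.votu_ids) + ";\n")


def save_model(model: ChronotypeModel, out_dir) -> None:
    """Write memberships.tsv, cooccurrence.tsv, consensus.nwk,
    k_per_bootstrap.tsv and a JSON manifest into ``out_dir``."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.membership_frame().to_csv(out / "memberships.tsv", sep="\t", index=False)
    pd.DataFrame(model.cooccurrence, index=model.votu_ids,
                 columns=model.votu_ids).rename_axis("votu_id").to_csv(
        out / "cooccurrence.tsv", sep="\t", float_format="%.10g")
    export_dendrogram(model, out / "consensus.nwk")
    pd.DataFrame({"bootstrap": range(1, model.n_bootstraps + 1),
                  "k_opt": model.per_bootstrap_k}).to_csv(
        out / "k_per_bootstrap.tsv", sep="\t", index=False)
    with open(out / "model.json", "w") as fh:
        json.dump({"seed": model.seed, "n_bootstraps": model.n_bootstraps,
                   "k_final": model.k_final, "n_votus": len(model.votu_ids)}, fh,
                  indent=2, sort_keys=True)


def load_memberships(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["votu_id"].astype(str), df["chronotype"].astype(int)))
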