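import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from chronotyper.chronoclustr import (bootstrap_consensus, cluster_collection,
                                      cluster_subgroup, elbow_k,
                                      export_dendrogram, kmeans_centroid_meta,
                                      partition_subgroups)


def planted_phase_series(n_per_group, phases, rng, amplitude=3.0, noise=0.3):
    t = np.arange(32)
    X, labels = [], []
    for g, phase in enumerate(phases):
        for _ in range(n_per_group):
            X.append(np.sin(2 * np.pi * (t + phase) / 12) * amplitude
                     + rng.normal(0, noise, 32))
            labels.append(g)
    X = np.asarray(X)
    X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
    return X, np.asarray(labels)


# ---------------------------------------------------------------------------
# subgroup partitioning
# ---------------------------------------------------------------------------

def test_partition_250_gives_100_100_50(rng):
    blocks = partition_subgroups([f"v{i}" for i in range(250)], 100, rng)
    assert [len(b) for b in blocks] == [100, 100, 50]
    assert sorted(sum(blocks, [])) == sorted(f"v{i}" for i in range(250))


def test_partition_merges_small_remainder(rng):
    blocks = partition_subgroups([f"v{i}" for i in range(205)], 100, rng)
    assert [len(b) for b in blocks] == [100, 105]


def test_partition_deterministic_and_order_independent():
    ids = [f"v{i}" for i in range(130)]
    b1 = partition_subgroups(ids, 50, np.random.default_rng(7))
    b2 = partition_subgroups(ids[::-1], 50, np.random.default_rng(7))
    assert b1 == b2


def test_partition_rejects_tiny_collections(rng):
    with pytest.raises(ValueError):
        partition_subgroups(["a", "b"], 100, rng)


# ---------------------------------------------------------------------------
# subgroup clustering
# ---------------------------------------------------------------------------

def test_two_separated_bundles_recovered(rng):
    X, truth = planted_phase_series(10, [0.0, 6.0], rng, noise=0.2)
    sub = cluster_subgroup(X, [f"v{i}" for i in range(20)])
    assert sub.k_opt == 2
    assert sub.silhouette > 0.8
    assert adjusted_rand_score(truth, sub.labels) == 1.0
    assert sub.centroids.shape == (2, 32)


def test_silhouette_argmax_matches_exhaustive_oracle(rng):
    X = rng.normal(size=(12, 8))
    sub = cluster_subgroup(X, list(range(12)))
    Z = linkage(pdist(X), method="complete")
    sq = squareform(pdist(X))
    best = max(range(2, 12),
               key=lambda k: silhouette_score(sq, fcluster(Z, k, "maxclust"),
                                              metric="precomputed"))
    assert sub.k_opt == best


def test_identical_series_degenerate_single_cluster():
    X = np.tile(np.arange(8.0), (5, 1))
    with pytest.warns(UserWarning, match="identical"):
        sub = cluster_subgroup(X, list(range(5)))
    assert sub.k_opt == 1


# ---------------------------------------------------------------------------
# elbow rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("wss,expected", [
    ((100, 10, 9, 8.5, 8), 2),          # sharp single elbow
    ((100, 80, 60, 40, 20), 2),         # linear decline: earliest qualifying k
])
def test_elbow_hand_examples(wss, expected):
    assert elbow_k(wss) == expected


def test_elbow_three_planted_clusters_with_kmeans_wss_oracle(rng):
    centers = np.array([[0, 0], [10, 0], [0, 10]])
    X = np.vstack([c + rng.normal(0, 0.3, size=(30, 2)) for c in centers])
    from sklearn.cluster import KMeans
    wss = [KMeans(k, n_init=10, random_state=0).fit(X).inertia_
           for k in range(1, 9)]
    assert elbow_k(wss) == 3


def test_elbow_requires_three_points():
    with pytest.raises(ValueError):
        elbow_k([10.0, 5.0])


# ---------------------------------------------------------------------------
# centroid meta-clustering
# ---------------------------------------------------------------------------

def test_kmeans_meta_recovers_three_remote_points(rng):
    anchors = np.array([[0.0, 0.0], [50.0, 0.0], [0.0, 50.0]])
    C = np.vstack([a + rng.normal(0, 0.1, size=(5, 2)) for a in anchors])
    wss, k_opt = kmeans_centroid_meta(C, np.random.default_rng(0))
    assert k_opt == 3
    total_ss = ((C - C.mean(0)) ** 2).sum()
    assert wss[0] == pytest.approx(total_ss)
    assert np.all(np.diff(np.minimum.accumulate(wss)) <= 1e-9)


def test_kmeans_meta_requires_four_centroids(rng):
    with pytest.raises(ValueError):
        kmeans_centroid_meta(np.ones((3, 2)), rng)


# ---------------------------------------------------------------------------
# full-collection clustering
# ---------------------------------------------------------------------------

def test_cluster_collection_extremes(rng):
    X = rng.normal(size=(6, 10))
    assert len(set(cluster_collection(X, 6))) == 6
    assert len(set(cluster_collection(X, 1))) == 1


def test_cluster_collection_recovers_four_phase_design(rng):
    X, truth = planted_phase_series(15, [0.0, 3.0, 6.0, 9.0], rng)
    labels = cluster_collection(X, 4)
    assert adjusted_rand_score(truth, labels) >= 0.9


def test_cluster_collection_rejects_k_above_n(rng):
    with pytest.raises(ValueError):
        cluster_collection(rng.normal(size=(4, 6)), 5)


# ---------------------------------------------------------------------------
# bootstrap consensus
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def consensus_fixture():
    rng = np.random.default_rng(21)
    X, truth = planted_phase_series(20, [0.0, 2.0, 4.0, 6.0, 8.0, 10.0], rng)
    ids = [f"v{i:03d}" for i in range(120)]
    model = bootstrap_consensus(X, ids, n_bootstraps=10, subgroup_size=40,
                                seed=5)
    return X, truth, ids, model


def test_consensus_matrix_invariants(consensus_fixture):
    _, _, ids, model = consensus_fixture
    co = model.cooccurrence
    assert np.allclose(co, co.T)
    assert np.allclose(np.diag(co), 1.0)
    scaled = co * model.n_bootstraps
    assert np.allclose(scaled, np.round(scaled))
    assert model.k_final == max(model.per_bootstrap_k)
    assert len(model.memberships) == len(ids)


def test_consensus_recovers_planted_groups(consensus_fixture):
    _, truth, ids, model = consensus_fixture
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    pred = [model.memberships[ids[i]] for i in order]
    assert adjusted_rand_score(truth[order], pred) >= 0.9


def test_consensus_deterministic_and_exchangeable(consensus_fixture):
    X, _, ids, model = consensus_fixture
    again = bootstrap_consensus(X, ids, n_bootstraps=10, subgroup_size=40,
                                seed=5)
    assert again.memberships == model.memberships
    # permuted input rows, same ids -> identical outputs (rng keyed to ids)
    perm = np.random.default_rng(3).permutation(len(ids))
    shuffled = bootstrap_consensus(X[perm], [ids[i] for i in perm],
                                   n_bootstraps=10, subgroup_size=40, seed=5)
    assert shuffled.memberships == model.memberships
    np.testing.assert_array_equal(shuffled.cooccurrence, model.cooccurrence)


def test_identical_pair_always_cooccurs_antiphase_never(rng):
    t = np.arange(32)
    base = np.sin(2 * np.pi * t / 12)
    X = np.vstack([base + rng.normal(0, 0.05, 32) for _ in range(6)]
                  + [-base + rng.normal(0, 0.05, 32) for _ in range(6)]
                  + [np.sin(2 * np.pi * (t + 3) / 12) + rng.normal(0, 0.05, 32)
                     for _ in range(6)])
    X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
    X[1] = X[0]                      # exact duplicate pair
    ids = [f"s{i:02d}" for i in range(18)]
    model = bootstrap_consensus(X, ids, n_bootstraps=8, subgroup_size=9, seed=2)
    i = model.votu_ids.index("s00")
    j = model.votu_ids.index("s01")
    k = model.votu_ids.index("s06")  # anti-phase member
    assert model.cooccurrence[i, j] == pytest.approx(1.0)
    assert model.cooccurrence[i, k] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# dendrogram export
# ---------------------------------------------------------------------------

def test_newick_export_round_trips(tmp_path, consensus_fixture):
    _, _, ids, model = consensus_fixture
    path = tmp_path / "consensus.nwk"
    export_dendrogram(model, path)
    import dendropy
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    assert leaves == set(ids)
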