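"""Graph construction, Louvain communities, subclustering and merging."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import protomap as pm
from protomap.cluster import NeighborGraph, jaccard_graph, knn_graph, louvain, merge_by_marker_correlation
from protomap.core import ValidationError
from protomap.markers import MarkerPanel

from conftest import brute_force_modularity, random_weighted_graphs


# ---------------------------------------------------------------- kNN graph

def test_three_equidistant_points_k2():
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    g = knn_graph(coords, k=2)
    for i, s in enumerate(g.neighbor_sets):
        assert set(s.tolist()) == {0, 1, 2} - {i}


def test_two_separated_blobs_have_no_cross_edges():
    rng = np.random.default_rng(0)
    a = rng.normal(size=(20, 3))
    b = rng.normal(size=(20, 3)) + 100.0
    coords = np.vstack([a, b])
    g = knn_graph(coords, k=10)
    # oracle: brute-force distance matrix
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    for i, s in enumerate(g.neighbor_sets):
        assert set(s.tolist()) == set(np.argsort(d[i], kind="stable")[:10].tolist())
        assert all((j < 20) == (i < 20) for j in s)


def test_duplicated_points_tie_break_deterministic():
    coords = np.zeros((6, 2))  # all identical -> all distances tie
    g = knn_graph(coords, k=3)
    for i, s in enumerate(g.neighbor_sets):
        expected = [j for j in range(6) if j != i][:3]
        assert s.tolist() == expected


def test_knn_requires_more_cells_than_k():
    with pytest.raises(ValidationError, match="k="):
        knn_graph(np.zeros((5, 2)), k=10)


# ------------------------------------------------------------- Jaccard graph

def test_jaccard_weights_from_set_arithmetic():
    sets = [
        np.array([1, 2, 3]),  # N(0)
        np.array([0, 2, 3]),  # N(1): mutual with 0; inter {2,3}, union {0,1,2,3}
        np.array([4, 5, 6]),  # N(2), N(3): identical sets but not adjacent
        np.array([4, 5, 6]),
        np.array([3, 5, 6]),  # (4,5) adjacent via 5 in N(4); disjoint sets
        np.array([0, 1, 2]),
        np.array([0, 1, 2]),
    ]
    g = jaccard_graph(sets)
    w = {(i, j): wt for i, j, wt in g.edges}
    assert w[(0, 1)] == pytest.approx(2 / 4)
    assert (2, 3) not in w  # neither lists the other: no candidate edge
    assert (4, 5) not in w  # adjacent but disjoint sets -> weight 0, dropped


def test_jaccard_ten_neighbor_overlap_five():
    n0 = np.arange(1, 11)  # includes node 1 -> (0,1) is a candidate edge
    n1 = np.concatenate([np.arange(6, 11), np.arange(20, 25)])  # overlap 5
    sets = [n0, n1] + [np.arange(2, 12)] * 28
    g = jaccard_graph([s.copy() for s in sets])
    w = {(i, j): wt for i, j, wt in g.edges}
    assert w[(0, 1)] == pytest.approx(5 / 15)


def test_jaccard_uniform_size_required():
    with pytest.raises(ValidationError, match="uniform"):
        jaccard_graph([np.array([1, 2]), np.array([0])])


# ------------------------------------------------------------------- Louvain

def test_two_cliques_split_cleanly():
    graphs = random_weighted_graphs()
    n, edges = graphs[0]  # two 4-cliques plus one bridge
    labels = louvain(NeighborGraph([np.empty(0)] * n, edges), seed=0)
    assert labels.n_clusters == 2
    assert len(set(labels.labels[:4])) == 1 and len(set(labels.labels[4:])) == 1


def test_single_node_graph():
    labels = louvain(NeighborGraph([np.empty(0)], []), seed=0)
    assert labels.labels.tolist() == [0]
    assert labels.modularity == 0.0


def test_isolated_nodes_get_own_clusters():
    labels = louvain(NeighborGraph([np.empty(0)] * 4, [(0, 1, 1.0)]), seed=0)
    assert labels.labels[0] == labels.labels[1]
    assert len(set(labels.labels.tolist())) == 3


def test_louvain_matches_enumeration_on_small_graphs():
    # a quick subset; the exhaustive sweep lives in the acceptance suite
    for n, edges in random_weighted_graphs()[:6]:
        best_q, _ = brute_force_modularity(n, edges)
        got = louvain(NeighborGraph([np.empty(0)] * n, edges), seed=1)
        assert got.modularity >= best_q - 1e-9


def test_louvain_deterministic_and_pass_log_nondecreasing():
    n, edges = random_weighted_graphs()[3]
    a = louvain(NeighborGraph([np.empty(0)] * n, edges), seed=7)
    b = louvain(NeighborGraph([np.empty(0)] * n, edges), seed=7)
    assert a.labels.tolist() == b.labels.tolist()
    assert np.all(np.diff(a.pass_log) >= -1e-12)


def test_louvain_agrees_with_igraph_on_modularity():
    igraph = pytest.importorskip("igraph")
    rng = np.random.default_rng(5)
    n = 60
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < 30) == (j < 30)
            p = 0.3 if same else 0.02
            if rng.uniform() < p:
                edges.append((i, j, float(rng.uniform(0.5, 1.0))))
    ours = louvain(NeighborGraph([np.empty(0)] * n, edges), seed=0)
    g = igraph.Graph(n=n, edges=[(i, j) for i, j, _ in edges])
    g.es["weight"] = [w for _, _, w in edges]
    theirs = g.community_multilevel(weights="weight")
    q_theirs = g.modularity(theirs.membership, weights="weight")
    assert ours.modularity >= q_theirs - 1e-6


def test_modularity_weight_scale_invariant():
    n, edges = random_weighted_graphs()[2]
    labels = louvain(NeighborGraph([np.empty(0)] * n, edges), seed=2).labels
    q1 = pm.modularity(n, edges, labels)
    q2 = pm.modularity(n, [(i, j, 10 * w) for i, j, w in edges], labels)
    assert q1 == pytest.approx(q2, abs=1e-12)


# ------------------------------------------------------------------- merging

def _marker_table_from_profiles(profiles, noise_sd=0.0, seed=0):
    """Build a marker table whose gene scores follow the given profiles."""
    rng = np.random.default_rng(seed)
    rows = []
    for cluster, profile in enumerate(profiles):
        noisy = np.maximum(profile + rng.normal(0, noise_sd, len(profile)), 0.0)
        for g, s in enumerate(noisy):
            if s > 0:
                rows.append((cluster, f"G{g}", 1.0, 0.5, 0.05, 1e-4, 1e-3, float(s)))
    return pd.DataFrame(rows, columns=pm.markers.MARKER_COLUMNS)


def test_merge_identity_when_target_equals_n():
    table = _marker_table_from_profiles(np.eye(4) * 3 + 0.5)
    mm = merge_by_marker_correlation(table, target_k=4)
    assert sorted(mm.mapping.values()) == [0, 1, 2, 3]


def test_identical_profiles_merge_first_at_height_zero():
    profiles = np.array(
        [[3.0, 0.1, 0.2, 1.0], [3.0, 0.1, 0.2, 1.0], [0.1, 4.0, 0.3, 0.1]]
    )
    mm = merge_by_marker_correlation(_marker_table_from_profiles(profiles), target_k=2)
    assert mm.mapping[0] == mm.mapping[1] != mm.mapping[2]
    assert mm.linkage_heights[0] == pytest.approx(0.0, abs=1e-12)


def test_merge_54_subclusters_back_to_9_programs():
    rng = np.random.default_rng(4)
    programs = rng.uniform(1.0, 4.0, size=(9, 60)) * (rng.uniform(size=(9, 60)) < 0.3)
    assignment = np.repeat(np.arange(9), 6)  # 54 subclusters
    profiles = programs[assignment]
    table = _marker_table_from_profiles(profiles, noise_sd=0.05, seed=5)
    mm = merge_by_marker_correlation(table, target_k=9)
    merged = np.asarray([mm.mapping[c] for c in range(54)])
    assert adjusted_rand_score(assignment, merged) == 1.0


def test_merge_invariant_to_cluster_relabeling():
    rng = np.random.default_rng(6)
    profiles = rng.uniform(0.0, 3.0, size=(8, 40))
    table = _marker_table_from_profiles(profiles)
    mm1 = merge_by_marker_correlation(table, target_k=3)
    perm = rng.permutation(8)
    relabeled = table.copy()
    relabeled["cluster"] = [int(np.flatnonzero(perm == c)[0]) for c in table["cluster"]]
    mm2 = merge_by_marker_correlation(relabeled, target_k=3)
    part1 = [mm1.mapping[int(c)] for c in range(8)]
    part2 = [mm2.mapping[int(np.flatnonzero(perm == c)[0])] for c in range(8)]
    assert adjusted_rand_score(part1, part2) == 1.0


def test_merge_target_too_large_rejected():
    table = _marker_table_from_profiles(np.eye(3) + 0.5)
    with pytest.raises(ValidationError, match="target_k"):
        merge_by_marker_correlation(table, target_k=5)


# -------------------------------------------------------------- subclustering

def _progenitor_with_neurons(seed=0, neuron_share=0.05):
    """Progenitor-dominated dataset with a planted neuron population."""
    config = pm.simdata.well_separated_config(
        n_cells=1200, n_genes=1200, n_types=5, n_batches=2, markers_per_type=30, seed=seed
    )
    weights = {t.name: (neuron_share if t.name == "type4" else (1 - neuron_share) / 4)
               for t in config.cell_types}
    config.stages = {"S1": weights}
    cm, truth = pm.generate_dataset(config)
    neuron_markers = [str(cm.gene_names[g]) for g in config.cell_types[4].marker_genes]
    panel = MarkerPanel(name="neuron", required_genes=frozenset(neuron_markers[:10]),
                        min_score=1.0, match_any=True)
    return cm, truth, panel


def test_subcluster_removes_planted_neurons():
    cm, truth, panel = _progenitor_with_neurons(seed=21)
    params = pm.PipelineParams(seed=21, run_qc=False)
    result = pm.subcluster_iterative(cm, np.zeros(cm.n_cells, dtype=int), [panel], params)
    assert len(result.iteration_log) <= 3
    survivors = truth.cell_type_labels[result.cell_index]
    assert (survivors == "type4").mean() < 0.01
    assert result.labels.n_clusters >= 3


def test_subcluster_without_matches_is_single_iteration():
    cm, truth, _ = _progenitor_with_neurons(seed=22, neuron_share=0.0)
    params = pm.PipelineParams(seed=22, run_qc=False)
    absent = MarkerPanel(name="neuron", required_genes=frozenset(["NO_SUCH_GENE"]),
                         min_score=1.0)
    result = pm.subcluster_iterative(cm, np.zeros(cm.n_cells, dtype=int), [absent], params)
    assert len(result.iteration_log) == 1
    assert len(result.cell_index) == cm.n_cells


def test_subcluster_empty_panel_list_is_vacuous():
    cm, _, _ = _progenitor_with_neurons(seed=23, neuron_share=0.0)
    params = pm.PipelineParams(seed=23, run_qc=False)
    result = pm.subcluster_iterative(cm, np.zeros(cm.n_cells, dtype=int), [], params)
    assert len(result.iteration_log) == 1
    assert len(result.cell_index) == cm.n_cells
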