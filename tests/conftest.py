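"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import scipy.stats

import protomap as pm


@pytest.fixture(scope="session")
def small_dataset():
    """1,200 cells, 6 well-separated types, 2 batches — fast and cleanly clusterable."""
    config = pm.simdata.well_separated_config(
        n_cells=1200, n_genes=1500, n_types=6, n_batches=2, seed=11
    )
    cm, truth = pm.generate_dataset(config)
    return config, cm, truth


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    """Pipeline result on the small dataset (QC through Louvain)."""
    _, cm, truth = small_dataset
    params = pm.PipelineParams(seed=11)
    result = pm.cluster_cells(cm, params)
    return result, truth


def iter_set_partitions(items):
    """All set partitions of a sequence (restricted-growth enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in iter_set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def brute_force_modularity(n_nodes: int, edges, resolution: float = 1.0):
    """Exhaustive maximum-modularity partition; oracle for small graphs."""
    best_q, best_labels = -np.inf, None
    for part in iter_set_partitions(range(n_nodes)):
        labels = np.empty(n_nodes, dtype=int)
        for c, block in enumerate(part):
            labels[block] = c
        q = pm.modularity(n_nodes, edges, labels, resolution)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def exact_rank_sum_p(x, y) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, k = len(pooled), len(x)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:k].sum() - k * (k + 1) / 2
    total = le = ge = 0
    for combo in itertools.combinations(range(n), k):
        u = ranks[list(combo)].sum() - k * (k + 1) / 2
        total += 1
        if u <= u_obs + 1e-12:
            le += 1
        if u >= u_obs - 1e-12:
            ge += 1
    return min(1.0, 2.0 * min(le / total, ge / total))


def random_weighted_graphs(max_nodes: int = 8, n_per_size: int = 4, seed: int = 0):
    """Deterministic fixture set of small weighted graphs for oracle tests."""
    rng = np.random.default_rng(seed)
    graphs = []
    # two 4-cliques joined by one bridge edge
    cliques = []
    for block in ([0, 1, 2, 3], [4, 5, 6, 7]):
        cliques += [(i, j, 1.0) for i, j in itertools.combinations(block, 2)]
    graphs.append((8, cliques + [(3, 4, 1.0)]))
    for n in range(3, max_nodes + 1):
        for _ in range(n_per_size):
            edges = []
            for i, j in itertools.combinations(range(n), 2):
                if rng.uniform() < 0.55:
                    edges.append((i, j, float(rng.uniform(0.1, 1.0))))
            if edges:
                graphs.append((n, edges))
    return graphs
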