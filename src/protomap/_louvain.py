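"""Seeded Louvain modularity optimization on weighted undirected graphs.

Classic two-phase scheme: repeated local moves (each node is removed from
its community and re-inserted where the modularity gain is largest), then
aggregation of communities into super-nodes, iterated until no move
improves modularity. Node visit order is shuffled with a seeded RNG, so
results are deterministic given the seed; the best partition over
``n_restarts`` independently seeded runs is returned. Modularity is the
weighted Newman-Girvan form with a resolution parameter:

    Q = sum_c [ S_in(c) / (2m) - gamma * (S_tot(c) / (2m))**2 ]

where S_in(c) counts internal edge weight twice and S_tot(c) is the total
degree of community c.
"""

from __future__ import annotations

import numpy as np

from .core import ValidationError

_EPS = 1e-12


def _adjacency(n_nodes: int, edges) -> list[dict[int, float]]:
    adj: list[dict[int, float]] = [dict() for _ in range(n_nodes)]
    for i, j, w in edges:
        i, j, w = int(i), int(j), float(w)
        if w <= 0:
            continue
        if i == j:
            adj[i][i] = adj[i].get(i, 0.0) + w
        else:
            adj[i][j] = adj[i].get(j, 0.0) + w
            adj[j][i] = adj[j].get(i, 0.0) + w
    return adj


def modularity(n_nodes: int, edges, labels, resolution: float = 1.0) -> float:
    """Modularity of a partition of a weighted undirected graph.

    ``edges`` is an iterable of (i, j, weight); self-loops allowed.
    """
    labels = np.asarray(labels)
    adj = _adjacency(n_nodes, edges)
    degree = np.zeros(n_nodes)
    for i in range(n_nodes):
        for j, w in adj[i].items():
            degree[i] += 2 * w if j == i else w
    two_m = degree.sum()
    if two_m <= 0:
        return 0.0
    s_in: dict = {}
    s_tot: dict = {}
    for i in range(n_nodes):
        c = labels[i]
        s_tot[c] = s_tot.get(c, 0.0) + degree[i]
        for j, w in adj[i].items():
            if labels[j] == c:
                s_in[c] = s_in.get(c, 0.0) + (2 * w if j == i else w)
    q = 0.0
    for c in s_tot:
        q += s_in.get(c, 0.0) / two_m - resolution * (s_tot[c] / two_m) ** 2
    return q


def _one_level(adj, degree, two_m, resolution, rng, init=None):
    """Local-move phase; returns (labels, improved).

    ``init`` seeds the starting community assignment (used by the
    node-level refinement pass); default is singletons.
    """
    n = len(adj)
    if init is None:
        labels = np.arange(n)
        s_tot = degree.copy()
    else:
        labels = np.asarray(init, dtype=int).copy()
        s_tot = np.zeros(n)
        for i in range(n):
            s_tot[labels[i]] += degree[i]
    order = rng.permutation(n)
    improved = False
    moved = True
    while moved:
        moved = False
        for i in order:
            ci = labels[i]
            ki = degree[i]
            # weight from i to each neighboring community (self-loop excluded)
            links: dict[int, float] = {}
            for j, w in adj[i].items():
                if j != i:
                    cj = labels[j]
                    links[cj] = links.get(cj, 0.0) + w
            s_tot[ci] -= ki
            base = links.get(ci, 0.0) - resolution * ki * s_tot[ci] / two_m
            best_c, best_gain = ci, base
            for c, wc in links.items():
                if c == ci:
                    continue
                gain = wc - resolution * ki * s_tot[c] / two_m
                if gain > best_gain + _EPS or (
                    abs(gain - best_gain) <= _EPS and c < best_c
                ):
                    best_c, best_gain = c, gain
            # a fresh singleton community has gain 0; take it when every
            # existing community (including the old one) is worse
            if best_gain < -_EPS:
                free = int(np.flatnonzero(s_tot == 0)[0]) if (s_tot == 0).any() else ci
                if s_tot[free] == 0:
                    best_c, best_gain = free, 0.0
            s_tot[best_c] += ki
            if best_c != ci:
                labels[i] = best_c
                moved = True
                improved = True
    return labels, improved


def _aggregate(adj, labels):
    """Collapse communities into super-nodes; returns (new_adj, mapping)."""
    comms = sorted(set(int(c) for c in labels))
    remap = {c: k for k, c in enumerate(comms)}
    new_n = len(comms)
    new_adj: list[dict[int, float]] = [dict() for _ in range(new_n)]
    for i in range(len(adj)):
        ci = remap[int(labels[i])]
        for j, w in adj[i].items():
            cj = remap[int(labels[j])]
            if i == j:
                new_adj[ci][ci] = new_adj[ci].get(ci, 0.0) + w
            elif i < j:
                if ci == cj:
                    new_adj[ci][ci] = new_adj[ci].get(ci, 0.0) + w
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                    new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
    return new_adj, remap


def _degrees(adj) -> np.ndarray:
    n = len(adj)
    degree = np.zeros(n)
    for i in range(n):
        for j, w in adj[i].items():
            degree[i] += 2 * w if j == i else w
    return degree


def louvain_partition(
    n_nodes: int,
    edges,
    resolution: float = 1.0,
    seed: int = 0,
    n_restarts: int = 5,
) -> tuple[np.ndarray, float, list[float]]:
    """Run Louvain; returns (labels, modularity, per-pass modularity log).

    Labels are contiguous integers ordered by first occurrence. The best of
    ``n_restarts`` seeded runs is kept; the pass log reports modularity after
    every local-move phase of the winning run (nondecreasing by construction).
    """
    if n_nodes == 0:
        raise ValidationError("empty graph")
    edges = [(int(i), int(j), float(w)) for i, j, w in edges]
    base_adj = _adjacency(n_nodes, edges)
    degree0 = _degrees(base_adj)
    two_m = degree0.sum()
    if two_m <= 0:
        # no edges: every node its own community
        labels = np.arange(n_nodes)
        return labels, 0.0, [0.0]

    def _contiguous(labels):
        remap: dict[int, int] = {}
        out = np.empty(len(labels), dtype=int)
        for i, c in enumerate(labels):
            c = int(c)
            if c not in remap:
                remap[c] = len(remap)
            out[i] = remap[c]
        return out

    def _q(labels) -> float:
        return modularity(n_nodes, edges, labels, resolution)

    def _hierarchy(adj, node_to_comm, rng, pass_log):
        while True:
            degree = _degrees(adj)
            labels, improved = _one_level(adj, degree, two_m, resolution, rng)
            node_to_comm = np.asarray([labels[c] for c in node_to_comm])
            pass_log.append(_q(node_to_comm))
            if not improved:
                return node_to_comm
            adj, remap = _aggregate(adj, labels)
            node_to_comm = np.asarray([remap[int(c)] for c in node_to_comm])

    degree0 = _degrees(base_adj)

    def _polish(node_to_comm, rng, pass_log):
        """Alternate node-level refinement on the original graph with fresh
        aggregated hierarchies until no single-node move improves."""
        while True:
            refined, improved = _one_level(
                base_adj, degree0, two_m, resolution, rng, init=_contiguous(node_to_comm)
            )
            if not improved:
                return node_to_comm
            node_to_comm = _contiguous(refined)
            pass_log.append(_q(node_to_comm))
            adj, remap = _aggregate(base_adj, node_to_comm)
            node_to_comm = _hierarchy(
                adj, np.asarray([remap[int(c)] for c in node_to_comm]), rng, pass_log
            )

    # iterated-local-search budget: cheap small graphs get many perturbation
    # rounds, large graphs rely on the hierarchy itself
    n_perturbations = min(60, 4096 // max(n_nodes, 1))

    best = None
    seeds = np.random.SeedSequence(seed).spawn(max(n_restarts, 1))
    for ss in seeds:
        rng = np.random.default_rng(ss)
        pass_log: list[float] = []
        node_to_comm = _hierarchy([dict(d) for d in base_adj], np.arange(n_nodes), rng, pass_log)
        node_to_comm = _polish(node_to_comm, rng, pass_log)
        q = pass_log[-1]
        # perturb-and-reoptimize: random partial reassignment, keep improvements
        for _ in range(n_perturbations):
            cand = _contiguous(node_to_comm)
            k = max(1, n_nodes // 3)
            idx = rng.choice(n_nodes, size=k, replace=False)
            cand[idx] = rng.integers(0, n_nodes, size=k)
            scratch: list[float] = [0.0]
            cand = _polish(_contiguous(cand), rng, scratch)
            q_cand = _q(cand)
            if q_cand > q + _EPS:
                node_to_comm, q = cand, q_cand
                pass_log.append(q)
        if best is None or q > best[1] + _EPS:
            best = (node_to_comm, q, pass_log)

    node_to_comm, q, pass_log = best
    # contiguous labels ordered by first occurrence
    remap: dict[int, int] = {}
    out = np.empty(n_nodes, dtype=int)
    for i, c in enumerate(node_to_comm):
        c = int(c)
        if c not in remap:
            remap[c] = len(remap)
        out[i] = remap[c]
    return out, float(q), pass_log
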