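"""kNN / Jaccard-graph / Louvain clustering, subclustering and merging.

The clustering graph is built from the k nearest neighbors of each cell in
the space of significant principal components; the symmetrized kNN edges
are re-weighted by the Jaccard similarity of the endpoints' neighbor sets,
so edges between cells whose neighborhoods disagree are down-weighted and
dropped when the neighborhoods are disjoint. Louvain modularity
optimization on that graph yields the cluster labels.

Subclustering reruns the normalize-reduce-cluster pipeline on a subset of
cells and iteratively removes subclusters matching exclusion marker panels
(e.g. contaminating neuronal populations) until none remain. Subclusters
are merged back to a target number of populations by hierarchically
clustering their marker gene-score profiles (average linkage on 1 - Pearson
r) and cutting the dendrogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from ._louvain import louvain_partition, modularity
from .core import CountMatrix, ValidationError
from .reduction import Embedding

__all__ = [
    "NeighborGraph",
    "ClusterLabels",
    "MergeMap",
    "knn_graph",
    "jaccard_graph",
    "louvain",
    "modularity",
    "subcluster_iterative",
    "merge_by_marker_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class NeighborGraph:
    """Per-cell neighbor sets plus (optionally) Jaccard-weighted edges."""

    neighbor_sets: list[np.ndarray]
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.neighbor_sets)


@dataclass
class ClusterLabels:
    labels: np.ndarray
    modularity: float
    seed: int
    resolution: float
    pass_log: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


@dataclass
class MergeMap:
    mapping: dict[int, int]
    linkage_heights: np.ndarray
    target_k: int

    def apply(self, labels: np.ndarray) -> np.ndarray:
        return np.asarray([self.mapping[c] for c in labels])


def knn_graph(embedding: Embedding | np.ndarray, k: int = 10) -> NeighborGraph:
    """Euclidean k nearest neighbors in the significant-PC space.

    Self is excluded; distance ties break toward the lower cell index.
    """
    if isinstance(embedding, Embedding):
        if embedding.n_significant < 1 and embedding.coordinates.shape[1] < 1:
            raise ValidationError("embedding has no components")
        coords = embedding.significant
    else:
        coords = np.asarray(embedding, dtype=np.float64)
    n = coords.shape[0]
    if n <= k:
        raise ValidationError(f"need more than k={k} cells, got {n}")

    neighbor_sets: list[np.ndarray] = []
    sq = np.einsum("ij,ij->i", coords, coords)
    chunk = max(1, int(2**24 // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * coords[start:stop] @ coords.T
        np.maximum(d2, 0.0, out=d2)
        for r in range(stop - start):
            i = start + r
            row = d2[r].copy()
            row[i] = np.inf  # exclude self
            # stable sort on distance -> lower index wins exact ties
            idx = np.argsort(row, kind="stable")[:k]
            neighbor_sets.append(idx.astype(np.int64))
    return NeighborGraph(neighbor_sets=neighbor_sets)


def jaccard_graph(neighbor_sets) -> NeighborGraph:
    """Weight symmetrized kNN edges by Jaccard similarity of neighbor sets.

    Candidate edges are pairs (i, j) with j in N(i) or i in N(j); the weight
    is |N(i) & N(j)| / |N(i) | N(j)|, and zero-weight edges are dropped.
    """
    if isinstance(neighbor_sets, NeighborGraph):
        neighbor_sets = neighbor_sets.neighbor_sets
    sets = [frozenset(int(x) for x in s) for s in neighbor_sets]
    k = len(sets[0]) if sets else 0
    for s in sets:
        if len(s) != k:
            raise ValidationError("neighbor sets must have uniform size")
    candidates = set()
    for i, s in enumerate(sets):
        for j in s:
            candidates.add((min(i, j), max(i, j)))
    edges = []
    for i, j in sorted(candidates):
        inter = len(sets[i] & sets[j])
        if inter:
            union = len(sets[i] | sets[j])
            edges.append((i, j, inter / union))
    return NeighborGraph(neighbor_sets=list(neighbor_sets), edges=edges)


def louvain(
    graph: NeighborGraph,
    resolution: float = 1.0,
    seed: int = 0,
    n_restarts: int = 5,
) -> ClusterLabels:
    """Louvain community detection on the Jaccard-weighted graph."""
    if graph.n_cells == 0:
        raise ValidationError("empty graph")
    labels, q, pass_log = louvain_partition(
        graph.n_cells, graph.edges, resolution=resolution, seed=seed, n_restarts=n_restarts
    )
    return ClusterLabels(
        labels=labels, modularity=q, seed=seed, resolution=resolution, pass_log=pass_log
    )


@dataclass
class SubclusterResult:
    labels: ClusterLabels
    cell_index: np.ndarray  # indices into the input CountMatrix
    iteration_log: list[dict]


def subcluster_iterative(
    counts: CountMatrix,
    labels,
    exclusion_panels,
    pipeline_params=None,
    keep_clusters=None,
    max_iterations: int = 10,
) -> SubclusterResult:
    """Subcluster selected cells, removing excluded populations iteratively.

    Restricts to cells of ``keep_clusters`` (default: all), reruns the
    normalize-reduce-cluster pipeline, annotates the subclusters against
    ``exclusion_panels`` (marker panels of populations to purge), removes
    matching subclusters and repeats until no subcluster matches.
    """
    from .markers import annotate_clusters, wilcoxon_markers
    from .pipeline import PipelineParams, cluster_cells

    params = pipeline_params or PipelineParams()
    labels = np.asarray(labels)
    if keep_clusters is None:
        mask = np.ones(counts.n_cells, dtype=bool)
    else:
        keep = set(int(c) for c in keep_clusters)
        mask = np.asarray([int(c) in keep for c in labels])
    cell_index = np.flatnonzero(mask)
    log: list[dict] = []

    for iteration in range(1, max_iterations + 1):
        if len(cell_index) == 0:
            raise ValidationError("subclustering removed every cell")
        sub = counts.subset_cells(cell_index)
        result = cluster_cells(sub, params)
        sub_labels = result.labels
        if not exclusion_panels:
            log.append({"iteration": iteration, "n_subclusters": sub_labels.n_clusters,
                        "removed": []})
            return SubclusterResult(sub_labels, cell_index, log)
        table = wilcoxon_markers(result.logmat, sub_labels.labels,
                                 min_frac_in=params.marker_min_frac_in,
                                 min_log2fc=params.marker_min_log2fc)
        calls = annotate_clusters(table, exclusion_panels)
        excluded = {c for c, lab in calls.items() if lab != "unknown"}
        log.append({
            "iteration": iteration,
            "n_subclusters": sub_labels.n_clusters,
            "removed": sorted(int(c) for c in excluded),
        })
        if not excluded:
            return SubclusterResult(sub_labels, cell_index, log)
        keep_mask = np.asarray([int(c) not in excluded for c in sub_labels.labels])
        cell_index = cell_index[keep_mask]

    raise ValidationError(
        f"subclustering did not converge in {max_iterations} iterations; log={log}"
    )


def merge_by_marker_correlation(marker_table, target_k: int, linkage: str = "average") -> MergeMap:
    """Merge clusters by cutting the dendrogram of marker-score correlations.

    Builds the clusters x genes gene-score matrix, correlates cluster rows
    (Pearson), and agglomerates on distance 1 - r; the tree is cut to yield
    exactly ``target_k`` merged clusters.
    """
    from .crosscorr import gene_score_matrix

    mat = gene_score_matrix(marker_table)
    clusters = list(mat.index)
    n = len(clusters)
    if target_k > n:
        raise ValidationError(f"target_k={target_k} exceeds {n} clusters")
    if target_k == n:
        return MergeMap({c: i for i, c in enumerate(clusters)}, np.zeros(0), target_k)

    x = mat.to_numpy(dtype=np.float64)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        raise ValidationError("cluster gene-score rows with zero variance cannot be correlated")
    r = np.corrcoef(x)
    dist = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    z = sch.linkage(ssd.squareform(dist, checks=False), method=linkage)
    cut = sch.fcluster(z, t=target_k, criterion="maxclust")
    if len(set(cut.tolist())) != target_k:
        raise ValidationError(
            f"dendrogram cut produced {len(set(cut.tolist()))} groups, wanted {target_k}"
        )
    # relabel merged ids by order of first appearance
    remap: dict[int, int] = {}
    mapping: dict = {}
    for c, g in zip(clusters, cut):
        g = int(g)
        if g not in remap:
            remap[g] = len(remap)
        mapping[c] = remap[g]
    return MergeMap(mapping=mapping, linkage_heights=z[:, 2].copy(), target_k=target_k)
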