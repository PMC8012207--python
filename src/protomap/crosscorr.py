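"""Cross-dataset cluster correspondence via marker gene-score correlation.

Each dataset's clusters are summarized as gene-score vectors over the
union of both datasets' marker genes (zeros where a gene is not a marker
of a cluster); cluster-to-cluster Pearson correlations over that shared
universe yield the correspondence matrix, thresholded into boolean calls.
A fidelity summary reduces the matrix to one value per shared cell type:
the maximum correlation between same-type cluster pairs, averaged across
types for the overall figure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CorrespondenceMatrix:
    r: pd.DataFrame  # clusters_A x clusters_B Pearson correlations
    gene_universe: list[str]
    threshold: float

    @property
    def calls(self) -> pd.DataFrame:
        return self.r >= self.threshold

    def row_argmax(self) -> dict:
        return {a: self.r.columns[int(np.argmax(self.r.loc[a].to_numpy()))] for a in self.r.index}


@dataclass
class FidelitySummary:
    per_type: dict[str, float]
    overall: float
    missing_types: list[str] = field(default_factory=list)


def gene_score_matrix(marker_table: pd.DataFrame, gene_universe=None) -> pd.DataFrame:
    """Clusters x genes matrix of gene scores (0 where not a marker)."""
    pivot = marker_table.pivot_table(
        index="cluster", columns="gene", values="gene_score", fill_value=0.0, aggfunc="max"
    )
    if gene_universe is not None:
        gene_universe = list(gene_universe)
        if not gene_universe:
            raise ValidationError("gene_universe must be nonempty")
        pivot = pivot.reindex(columns=gene_universe, fill_value=0.0)
    pivot.columns = [str(c) for c in pivot.columns]
    return pivot.astype(np.float64)


def cluster_correspondence(
    mat_a: pd.DataFrame,
    mat_b: pd.DataFrame,
    ortholog_map: dict[str, str] | None = None,
    threshold: float = 0.4,
) -> CorrespondenceMatrix:
    """Pearson correspondence between two cluster gene-score matrices.

    ``ortholog_map`` maps dataset-A gene names to dataset-B names (default:
    identity, i.e. shared gene symbols). The correlation universe is the
    union of both datasets' marker genes, expressed in A's namespace; genes
    absent from a dataset contribute zeros. Zero-variance rows yield r = 0
    with a warning.
    """
    if ortholog_map is None:
        ortholog_map = {}
    inverse = {b: a for a, b in ortholog_map.items()}
    genes_a = set(map(str, mat_a.columns))
    genes_b_in_a = {inverse.get(g, g) for g in map(str, mat_b.columns)}
    universe = sorted(genes_a | genes_b_in_a)
    # only genes that can be expressed in both namespaces are comparable
    universe = [g for g in universe if ortholog_map.get(g, g) is not None]
    if not universe:
        raise ValidationError("empty shared gene universe")

    a = mat_a.reindex(columns=universe, fill_value=0.0).to_numpy(dtype=np.float64)
    b_cols = [ortholog_map.get(g, g) for g in universe]
    b = mat_b.reindex(columns=b_cols, fill_value=0.0).to_numpy(dtype=np.float64)

    a_c = a - a.mean(axis=1, keepdims=True)
    b_c = b - b.mean(axis=1, keepdims=True)
    a_sd = np.sqrt((a_c**2).sum(axis=1))
    b_sd = np.sqrt((b_c**2).sum(axis=1))
    bad_a = a_sd == 0
    bad_b = b_sd == 0
    if bad_a.any() or bad_b.any():
        logger.warning(
            "zero-variance gene-score rows: %d in A, %d in B; r set to 0",
            int(bad_a.sum()),
            int(bad_b.sum()),
        )
    r = (a_c @ b_c.T) / np.outer(np.where(bad_a, 1.0, a_sd), np.where(bad_b, 1.0, b_sd))
    r[bad_a, :] = 0.0
    r[:, bad_b] = 0.0
    r = np.clip(r, -1.0, 1.0)
    rdf = pd.DataFrame(r, index=mat_a.index, columns=mat_b.index)
    return CorrespondenceMatrix(r=rdf, gene_universe=universe, threshold=threshold)


def fidelity_summary(
    correspondence: CorrespondenceMatrix,
    type_labels_a: dict,
    type_labels_b: dict,
) -> FidelitySummary:
    """Per-cell-type max same-type correlation; overall = mean over types.

    A = query clusters, B = reference clusters; ``type_labels_*`` map
    cluster ids to cell-type labels. Types present on only one side are
    reported as missing and excluded from the mean.
    """
    r = correspondence.r
    types_a = {t for c, t in type_labels_a.items() if c in r.index}
    types_b = {t for c, t in type_labels_b.items() if c in r.columns}
    shared = sorted(types_a & types_b)
    missing = sorted((types_a | types_b) - set(shared))
    if not shared:
        raise ValidationError("no cell types shared between the two datasets")
    per_type = {}
    for t in shared:
        rows = [c for c in r.index if type_labels_a.get(c) == t]
        cols = [c for c in r.columns if type_labels_b.get(c) == t]
        per_type[t] = float(r.loc[rows, cols].to_numpy().max())
    overall = float(np.mean(list(per_type.values())))
    return FidelitySummary(per_type=per_type, overall=overall, missing_types=missing)


def read_ortholog_map(path) -> dict[str, str]:
    """Two-column TSV (gene_a <tab> gene_b) -> mapping dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise ValidationError("ortholog map needs two columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
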