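"""Cluster marker detection, gene scores, and rule-based annotation.

Markers are called one-vs-rest with the Wilcoxon rank-sum test. The gene
score integrates fold enrichment and specificity:

    gene_score = log2FC * frac_in / max(frac_out, 0.01)

where log2FC is the difference of mean log2 expression in vs out of the
cluster and frac_in / frac_out are detection fractions. The floor on
frac_out prevents division blow-up for perfectly specific markers; the
formula is pluggable. Annotation assigns each cluster a cell-type label
from marker panels (required/forbidden genes with a minimum score), with
the progenitor-specific rule that a progenitor cluster is called radial
glia if a neurogenic panel also passes and neuroepithelial otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import scipy.stats

from .core import NormalizedMatrix, ValidationError, check_labels

logger = logging.getLogger(__name__)

MARKER_COLUMNS = [
    "cluster",
    "gene",
    "log2_fold_enrichment",
    "frac_in",
    "frac_out",
    "p_value",
    "p_adjusted",
    "gene_score",
]


def rank_sum_test(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value for two samples.

    ``method`` follows scipy's convention: "exact" enumerates the null
    distribution (valid without ties), "asymptotic" uses the tie-corrected
    normal approximation, "auto" chooses exact for small tie-free samples.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("rank_sum_test requires nonempty samples")
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def default_gene_score(log2fc: np.ndarray, frac_in: np.ndarray, frac_out: np.ndarray) -> np.ndarray:
    return log2fc * frac_in / np.maximum(frac_out, 0.01)


def wilcoxon_markers(
    logmat: NormalizedMatrix | np.ndarray,
    labels,
    min_frac_in: float = 0.1,
    min_log2fc: float = 0.25,
    method: str = "auto",
    score_fn: Callable = default_gene_score,
    gene_names=None,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon markers for every cluster.

    Genes failing the detection-fraction or fold-change prefilter are not
    tested; p-values are Benjamini-Hochberg adjusted across the tested
    genes within each cluster. Rows are sorted by gene score (descending)
    within cluster. Clusters with fewer than 3 cells are skipped.
    """
    if isinstance(logmat, NormalizedMatrix):
        x = np.asarray(logmat.values.todense(), dtype=np.float64)
        gene_names = logmat.gene_names
    else:
        x = np.asarray(logmat, dtype=np.float64)
        if gene_names is None:
            gene_names = np.asarray([f"g{i}" for i in range(x.shape[0])], dtype=object)
    labels = check_labels(labels, x.shape[1])
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValidationError("marker detection requires at least 2 clusters")

    detected = x > 0
    rows = []
    for c in clusters:
        in_mask = labels == c
        n_in = int(in_mask.sum())
        if n_in < 3:
            logger.warning("cluster %s has %d < 3 cells; skipped", c, n_in)
            continue
        out_mask = ~in_mask
        mean_in = x[:, in_mask].mean(axis=1)
        mean_out = x[:, out_mask].mean(axis=1)
        log2fc = mean_in - mean_out
        frac_in = detected[:, in_mask].mean(axis=1)
        frac_out = detected[:, out_mask].mean(axis=1)
        keep = (frac_in >= min_frac_in) & (log2fc >= min_log2fc)
        idx = np.flatnonzero(keep)
        if len(idx) == 0:
            continue
        pvals = np.empty(len(idx))
        for r, g in enumerate(idx):
            pvals[r] = rank_sum_test(x[g, in_mask], x[g, out_mask], method=method)
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
        padj = np.clip(scipy.stats.false_discovery_control(pvals, method="bh"), None, 1.0)
        score = score_fn(log2fc[idx], frac_in[idx], frac_out[idx])
        for r, g in enumerate(idx):
            rows.append(
                (
                    int(c) if np.issubdtype(np.asarray(labels).dtype, np.integer) else c,
                    str(gene_names[g]),
                    float(log2fc[g]),
                    float(frac_in[g]),
                    float(frac_out[g]),
                    float(pvals[r]),
                    float(padj[r]),
                    float(score[r]),
                )
            )
    table = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    table = table.sort_values(
        ["cluster", "gene_score"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    return table


@dataclass
class MarkerPanel:
    """A cell-type rule: required/forbidden genes with a score threshold.

    A cluster passes when every required gene (or any, with
    ``match_any=True``) is a marker with gene_score >= min_score, and no
    forbidden gene reaches min_score.
    """

    name: str
    required_genes: frozenset = frozenset()
    forbidden_genes: frozenset = frozenset()
    min_score: float = 0.5
    match_any: bool = False

    def __post_init__(self):
        self.required_genes = frozenset(self.required_genes)
        self.forbidden_genes = frozenset(self.forbidden_genes)
        if self.required_genes & self.forbidden_genes:
            raise ValidationError(
                f"panel {self.name!r}: required and forbidden genes overlap"
            )

    def passes(self, scores: dict[str, float]) -> bool:
        req = [scores.get(g, 0.0) >= self.min_score for g in self.required_genes]
        if self.required_genes:
            ok = any(req) if self.match_any else all(req)
            if not ok:
                return False
        for g in self.forbidden_genes:
            if scores.get(g, 0.0) >= self.min_score:
                return False
        return True

    def mean_required_score(self, scores: dict[str, float]) -> float:
        if not self.required_genes:
            return 0.0
        return float(np.mean([scores.get(g, 0.0) for g in self.required_genes]))


PROGENITOR_PANEL = "progenitor"
NEUROGENIC_PANEL = "neurogenic"
RADIAL_GLIA_LABEL = "radial glia"
NEUROEPITHELIAL_LABEL = "neuroepithelial"


def load_panels(path=None) -> list[MarkerPanel]:
    """Load marker panels from YAML (default: the shipped panel file)."""
    import yaml

    if path is None:
        path = Path(__file__).parent / "data" / "default_panels.yaml"
    spec = yaml.safe_load(Path(path).read_text())
    panels = []
    for entry in spec["panels"]:
        panels.append(
            MarkerPanel(
                name=entry["name"],
                required_genes=frozenset(entry.get("required_genes", [])),
                forbidden_genes=frozenset(entry.get("forbidden_genes", [])),
                min_score=float(entry.get("min_score", 0.5)),
                match_any=bool(entry.get("match_any", False)),
            )
        )
    return panels


def annotate_clusters(
    marker_table: pd.DataFrame,
    panels: list[MarkerPanel],
    precedence: list[list[str]] | None = None,
) -> dict:
    """Assign a cell-type label to every cluster in the marker table.

    Panels are evaluated in precedence order (default: one tier per panel,
    in list order). The progenitor panel triggers the radial-glia /
    neuroepithelial split: progenitor clusters are labeled radial glia when
    the neurogenic panel also passes, neuroepithelial otherwise. Clusters
    matching no panel are labeled "unknown"; ties within a precedence tier
    go to the panel with the highest mean required-gene score.
    """
    if not panels:
        raise ValidationError("panels must be nonempty")
    by_name = {p.name: p for p in panels}
    neurogenic = by_name.get(NEUROGENIC_PANEL)
    if precedence is None:
        precedence = [[p.name] for p in panels if p.name != NEUROGENIC_PANEL]

    out: dict = {}
    for cluster, grp in marker_table.groupby("cluster"):
        scores = dict(zip(grp["gene"], grp["gene_score"]))
        label = "unknown"
        for tier in precedence:
            matches = [by_name[n] for n in tier if n in by_name and by_name[n].passes(scores)]
            if not matches:
                continue
            if len(matches) > 1:
                matches.sort(key=lambda p: -p.mean_required_score(scores))
                logger.info(
                    "cluster %s matches %s; tie broken by mean gene score",
                    cluster,
                    [p.name for p in matches],
                )
            panel = matches[0]
            if panel.name == PROGENITOR_PANEL:
                if neurogenic is not None and neurogenic.passes(scores):
                    label = RADIAL_GLIA_LABEL
                else:
                    label = NEUROEPITHELIAL_LABEL
            else:
                label = panel.name
            break
        out[cluster] = label
    return out
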