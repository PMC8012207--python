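"""Cell-level quality control.

Two filter sets: the standard per-cell filters (minimum detected genes,
maximum mitochondrial count fraction) and the stricter input filters used
before RNA-velocity estimation (minimum total, spliced and unspliced
counts). Thresholds are inclusive on the keep side: a cell with exactly
``min_genes_per_cell`` detected genes, or a mitochondrial fraction exactly
at ``max_mito_fraction``, is retained.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, asdict

import numpy as np

from .core import CountMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 500
    max_mito_fraction: float = 0.10
    velocity_min_total: int = 200
    velocity_min_spliced: int = 20
    velocity_min_unspliced: int = 10
    mito_prefix: str = "MT-"

    def validate(self) -> None:
        for name in (
            "min_genes_per_cell",
            "velocity_min_total",
            "velocity_min_spliced",
            "velocity_min_unspliced",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValidationError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_out: int
    removed_low_genes: int
    removed_high_mito: int
    keep_mask: np.ndarray
    low_genes_mask: np.ndarray
    high_mito_mask: np.ndarray

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("keep_mask", "low_genes_mask", "high_mito_mask"):
            d[k] = [bool(v) for v in d[k]]
        return d


def mito_gene_mask(gene_names, prefix: str = "MT-") -> np.ndarray:
    """Boolean mask of mitochondrial genes by name prefix (regex allowed)."""
    pat = re.compile(prefix)
    return np.asarray([bool(pat.match(str(g))) for g in gene_names])


def filter_cells(counts: CountMatrix, thresholds: QCThresholds | None = None) -> tuple[CountMatrix, QCReport]:
    """Remove low-complexity and high-mitochondrial cells.

    Keeps cells with at least ``min_genes_per_cell`` detected genes and a
    mitochondrial count fraction no greater than ``max_mito_fraction``.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    if counts.gene_names is None or len(counts.gene_names) == 0:
        raise ValidationError("gene names are required for QC filtering")

    genes_per_cell = counts.genes_per_cell()
    totals = counts.cell_totals().astype(np.float64)
    mito = mito_gene_mask(counts.gene_names, thresholds.mito_prefix)
    mito_counts = np.asarray(counts.counts[mito, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)

    low_genes = genes_per_cell < thresholds.min_genes_per_cell
    high_mito = mito_frac > thresholds.max_mito_fraction
    keep = ~(low_genes | high_mito)
    if not keep.any():
        raise ValidationError("QC removed every cell; check thresholds and input")

    report = QCReport(
        n_cells_in=counts.n_cells,
        n_cells_out=int(keep.sum()),
        removed_low_genes=int(low_genes.sum()),
        removed_high_mito=int(high_mito.sum()),
        keep_mask=keep,
        low_genes_mask=low_genes,
        high_mito_mask=high_mito,
    )
    logger.info(
        "QC: %d/%d cells kept (%d low-gene, %d high-mito)",
        report.n_cells_out,
        report.n_cells_in,
        report.removed_low_genes,
        report.removed_high_mito,
    )
    return counts.subset_cells(keep), report


def filter_cells_velocity(counts: CountMatrix, thresholds: QCThresholds | None = None) -> CountMatrix:
    """Apply the velocity input filters (all minima inclusive)."""
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    if "spliced" not in counts.layers or "unspliced" not in counts.layers:
        raise ValidationError("spliced and unspliced layers are required")
    total = counts.cell_totals()
    spliced = np.asarray(counts.layers["spliced"].sum(axis=0)).ravel()
    unspliced = np.asarray(counts.layers["unspliced"].sum(axis=0)).ravel()
    keep = (
        (total >= thresholds.velocity_min_total)
        & (spliced >= thresholds.velocity_min_spliced)
        & (unspliced >= thresholds.velocity_min_unspliced)
    )
    logger.info("velocity QC: %d/%d cells kept", int(keep.sum()), counts.n_cells)
    return counts.subset_cells(keep)
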