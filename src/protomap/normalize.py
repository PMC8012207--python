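"""Batch-wise depth normalization and log2 transform.

Each batch is normalized independently: every cell is scaled so its total
equals the median raw total of its batch, then the batches are concatenated.
(Equivalently: scale each cell to the batch-maximum total, then rescale the
batch by median/max — the two factors compose to median/total and both are
recorded in the provenance for auditability.) The log transform is
``log2(x + 1)``, which preserves sparsity.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .core import CountMatrix, NormalizedMatrix, ValidationError


def batch_normalize(counts: CountMatrix, batch_labels=None) -> NormalizedMatrix:
    """Scale every cell's counts so its total equals its batch's median total."""
    if batch_labels is None:
        batch_labels = counts.batch_labels()
    batch_labels = np.asarray(batch_labels)
    if batch_labels.shape != (counts.n_cells,):
        raise ValidationError("batch_labels must have one entry per cell")

    totals = counts.cell_totals().astype(np.float64)
    if np.any(totals <= 0):
        raise ValidationError(
            f"{int((totals <= 0).sum())} cells have zero total counts; run QC first"
        )

    factors = np.empty(counts.n_cells, dtype=np.float64)
    provenance: dict = {"method": "batch_median", "batches": {}}
    for batch in np.unique(batch_labels):
        in_batch = batch_labels == batch
        batch_totals = totals[in_batch]
        med = float(np.median(batch_totals))  # midpoint of two for even n
        mx = float(batch_totals.max())
        factors[in_batch] = med / batch_totals
        provenance["batches"][str(batch)] = {
            "n_cells": int(in_batch.sum()),
            "median_total": med,
            "max_total": mx,
            "to_max_then_rescale": mx and med / mx,
        }

    values = (counts.counts.astype(np.float64) @ sp.diags(factors)).tocsc()
    return NormalizedMatrix(
        values,
        counts.gene_names,
        counts.barcodes,
        metadata=counts.metadata,
        provenance=provenance,
    )


def log_transform(norm: NormalizedMatrix) -> NormalizedMatrix:
    """Elementwise log2(x + 1); zeros stay zero, sparsity is preserved."""
    values = norm.values.copy()
    if values.nnz and values.data.min() < 0:
        raise ValidationError("log transform requires nonnegative input")
    values.data = np.log2(values.data + 1.0)
    provenance = dict(norm.provenance)
    provenance["log"] = "log2(x+1)"
    return NormalizedMatrix(
        values, norm.gene_names, norm.barcodes, metadata=norm.metadata, provenance=provenance
    )
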