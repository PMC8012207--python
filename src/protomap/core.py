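"""Core in-memory containers shared by every pipeline stage.

Matrices are stored genes x cells (the orientation of the MTX files the
pipeline reads and writes). Per-cell metadata travels with the matrix so
that every subsetting operation keeps counts, barcodes and annotations
aligned by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ValidationError(ValueError):
    """Raised when an input object violates a documented contract."""


def _as_csc(m) -> sp.csc_matrix:
    if not sp.issparse(m):
        m = sp.csc_matrix(np.asarray(m))
    return m.tocsc()


@dataclass
class CountMatrix:
    """Sparse genes x cells count matrix with optional layers and metadata.

    Parameters
    ----------
    counts
        Sparse (or dense, converted) genes x cells matrix of nonnegative
        counts.
    gene_names, barcodes
        Row and column identifiers; lengths must match the matrix shape.
    metadata
        Per-cell table aligned with ``barcodes`` (columns such as
        ``batch``, ``stage``, ``region``).
    layers
        Optional named matrices with the same shape as ``counts``
        (e.g. ``"spliced"``/``"unspliced"``).
    """

    counts: sp.spmatrix
    gene_names: np.ndarray
    barcodes: np.ndarray
    metadata: pd.DataFrame | None = None
    layers: dict[str, sp.spmatrix] = field(default_factory=dict)

    def __post_init__(self):
        self.counts = _as_csc(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.counts.shape != (len(self.gene_names), len(self.barcodes)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_names)} genes x {len(self.barcodes)} cells"
            )
        if self.metadata is not None:
            if len(self.metadata) != self.n_cells:
                raise ValidationError(
                    f"metadata has {len(self.metadata)} rows for {self.n_cells} cells"
                )
            self.metadata = self.metadata.reset_index(drop=True)
        for name, layer in list(self.layers.items()):
            layer = _as_csc(layer)
            if layer.shape != self.counts.shape:
                raise ValidationError(f"layer {name!r} shape {layer.shape} != counts")
            self.layers[name] = layer

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of genes with count > 0 in each cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def subset_cells(self, index) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given cell indices/mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return CountMatrix(
            counts=self.counts[:, index],
            gene_names=self.gene_names,
            barcodes=self.barcodes[index],
            metadata=None if self.metadata is None else self.metadata.iloc[index],
            layers={k: v[:, index] for k, v in self.layers.items()},
        )

    def batch_labels(self, column: str = "batch") -> np.ndarray:
        if self.metadata is None or column not in self.metadata:
            raise ValidationError(f"metadata column {column!r} is required")
        return self.metadata[column].to_numpy()


@dataclass
class NormalizedMatrix:
    """Genes x cells real-valued expression with normalization provenance."""

    values: sp.spmatrix
    gene_names: np.ndarray
    barcodes: np.ndarray
    metadata: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = _as_csc(self.values).astype(np.float64)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.values.shape != (len(self.gene_names), len(self.barcodes)):
            raise ValidationError("values shape does not match gene/barcode names")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("normalized values must be nonnegative")
        if self.metadata is not None:
            self.metadata = self.metadata.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index) -> "NormalizedMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return NormalizedMatrix(
            values=self.values[:, index],
            gene_names=self.gene_names,
            barcodes=self.barcodes[index],
            metadata=None if self.metadata is None else self.metadata.iloc[index],
            provenance=dict(self.provenance),
        )

    def batch_labels(self, column: str = "batch") -> np.ndarray:
        if self.metadata is None or column not in self.metadata:
            raise ValidationError(f"metadata column {column!r} is required")
        return self.metadata[column].to_numpy()


def check_labels(labels, n_cells: int, name: str = "labels") -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (n_cells,):
        raise ValidationError(f"{name} must have one entry per cell")
    return labels
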