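"""Matrix Market + TSV sidecar I/O for count matrices and result tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import CountMatrix, NormalizedMatrix, ValidationError

SPLICED_SUFFIX = ".spliced.mtx"
UNSPLICED_SUFFIX = ".unspliced.mtx"


def _read_tsv_column(path) -> np.ndarray:
    names = pd.read_csv(path, sep="\t", header=None).iloc[:, 0]
    return names.astype(str).to_numpy(dtype=object)


def _dedup(names: np.ndarray) -> tuple[np.ndarray, int]:
    """Disambiguate duplicate names with .1/.2/... suffixes."""
    seen: dict[str, int] = {}
    out = []
    n_dup = 0
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
            n_dup += 1
        else:
            seen[name] = 0
            out.append(name)
    return np.asarray(out, dtype=object), n_dup


def read_counts(
    mtx_path,
    genes_path,
    barcodes_path,
    metadata_path=None,
    require_integer: bool = True,
) -> CountMatrix:
    """Read a genes x cells MTX with gene/barcode TSV sidecars.

    Spliced/unspliced layers are picked up automatically from sibling files
    named ``<stem>.spliced.mtx`` / ``<stem>.unspliced.mtx``.
    """
    mtx_path = Path(mtx_path)
    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # noqa: BLE001 - surface a uniform error type
        raise ValidationError(f"malformed MTX file {mtx_path}: {exc}") from exc
    mat = sp.csc_matrix(mat)
    if require_integer:
        if mat.nnz and not np.allclose(mat.data, np.round(mat.data)):
            raise ValidationError(f"{mtx_path} contains non-integer entries")
        mat = mat.astype(np.int64)

    genes = _read_tsv_column(genes_path)
    barcodes = _read_tsv_column(barcodes_path)
    if mat.shape != (len(genes), len(barcodes)):
        raise ValidationError(
            f"MTX shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes, {len(barcodes)} barcodes)"
        )
    genes, n_dup = _dedup(genes)
    if n_dup:
        import logging

        logging.getLogger(__name__).warning(
            "disambiguated %d duplicate gene names", n_dup
        )

    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, sep="\t")
        if len(metadata) != len(barcodes):
            raise ValidationError(
                f"metadata has {len(metadata)} rows for {len(barcodes)} barcodes"
            )

    layers = {}
    base = mtx_path.with_suffix("")  # strip ".mtx"
    for name, suffix in (("spliced", SPLICED_SUFFIX), ("unspliced", UNSPLICED_SUFFIX)):
        sib = base.parent / (base.name + suffix)
        if sib.exists():
            layer = sp.csc_matrix(scipy.io.mmread(sib))
            layers[name] = layer.astype(np.int64) if require_integer else layer
    return CountMatrix(mat, genes, barcodes, metadata=metadata, layers=layers)


def write_counts(cm: CountMatrix, out_prefix) -> dict[str, str]:
    """Write MTX + genes.tsv + barcodes.tsv (+ metadata.tsv, layers).

    Returns a map of artifact name -> written path.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    mtx = out_prefix.parent / (out_prefix.name + ".mtx")
    scipy.io.mmwrite(str(mtx), cm.counts)
    paths["counts"] = str(mtx)
    genes = out_prefix.parent / (out_prefix.name + ".genes.tsv")
    pd.Series(cm.gene_names).to_csv(genes, sep="\t", header=False, index=False)
    paths["genes"] = str(genes)
    bcs = out_prefix.parent / (out_prefix.name + ".barcodes.tsv")
    pd.Series(cm.barcodes).to_csv(bcs, sep="\t", header=False, index=False)
    paths["barcodes"] = str(bcs)
    if cm.metadata is not None:
        meta = out_prefix.parent / (out_prefix.name + ".metadata.tsv")
        cm.metadata.to_csv(meta, sep="\t", index=False)
        paths["metadata"] = str(meta)
    for name, suffix in (("spliced", SPLICED_SUFFIX), ("unspliced", UNSPLICED_SUFFIX)):
        if name in cm.layers:
            sib = out_prefix.parent / (out_prefix.name + suffix)
            scipy.io.mmwrite(str(sib), cm.layers[name])
            paths[name] = str(sib)
    return paths


def write_normalized(nm: NormalizedMatrix, out_prefix) -> dict[str, str]:
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    mtx = out_prefix.parent / (out_prefix.name + ".mtx")
    scipy.io.mmwrite(str(mtx), nm.values)
    paths["values"] = str(mtx)
    genes = out_prefix.parent / (out_prefix.name + ".genes.tsv")
    pd.Series(nm.gene_names).to_csv(genes, sep="\t", header=False, index=False)
    paths["genes"] = str(genes)
    bcs = out_prefix.parent / (out_prefix.name + ".barcodes.tsv")
    pd.Series(nm.barcodes).to_csv(bcs, sep="\t", header=False, index=False)
    paths["barcodes"] = str(bcs)
    prov = out_prefix.parent / (out_prefix.name + ".provenance.json")
    prov.write_text(json.dumps(nm.provenance, indent=2, default=str))
    paths["provenance"] = str(prov)
    return paths


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets in GMT format: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"GMT line with fewer than 3 fields: {line[:50]}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets
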