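"""End-to-end pipeline: QC -> normalize -> reduce -> cluster -> annotate.

`cluster_cells` is the in-memory workhorse reused by subclustering and by
the file-based `run_pipeline`, which additionally writes every artifact and
a manifest of config/seed/file hashes so runs are reproducible and
auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .cluster import ClusterLabels, jaccard_graph, knn_graph, louvain, merge_by_marker_correlation
from .core import CountMatrix, NormalizedMatrix, ValidationError
from .markers import annotate_clusters, load_panels, wilcoxon_markers
from .normalize import batch_normalize, log_transform
from .qc import QCThresholds, filter_cells
from .reduction import Embedding, VariableGeneParams, reduce_dimensions

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Numeric knobs of the in-memory pipeline (QC through Louvain)."""

    qc: QCThresholds = field(default_factory=QCThresholds)
    var_genes: VariableGeneParams = field(default_factory=VariableGeneParams)
    n_pcs: int = 50
    n_permutations: int = 25
    k_neighbors: int = 10
    resolution: float = 1.0
    seed: int = 0
    batch_column: str = "batch"
    target_k: int = 9
    correspondence_threshold: float = 0.4
    marker_min_frac_in: float = 0.1
    marker_min_log2fc: float = 0.25
    run_qc: bool = True


@dataclass
class PipelineResult:
    counts: CountMatrix
    logmat: NormalizedMatrix
    embedding: Embedding
    variable_genes: list[str]
    labels: ClusterLabels
    qc_report: object | None = None


def cluster_cells(counts: CountMatrix, params: PipelineParams | None = None) -> PipelineResult:
    """Run QC, normalization, reduction and Jaccard-Louvain clustering."""
    params = params or PipelineParams()
    qc_report = None
    if params.run_qc:
        counts, qc_report = filter_cells(counts, params.qc)
    batches = counts.batch_labels(params.batch_column)
    norm = batch_normalize(counts, batches)
    logmat = log_transform(norm)
    embedding, genes = reduce_dimensions(
        logmat,
        batches,
        var_params=params.var_genes,
        n_components=min(params.n_pcs, counts.n_cells - 1),
        n_permutations=params.n_permutations,
        seed=params.seed,
    )
    graph = jaccard_graph(knn_graph(embedding, k=params.k_neighbors))
    labels = louvain(graph, resolution=params.resolution, seed=params.seed)
    return PipelineResult(
        counts=counts,
        logmat=logmat,
        embedding=embedding,
        variable_genes=genes,
        labels=labels,
        qc_report=qc_report,
    )


@dataclass
class PipelineConfig:
    """File-based pipeline configuration; round-trips losslessly via YAML."""

    counts_path: str = ""
    genes_path: str = ""
    barcodes_path: str = ""
    metadata_path: str | None = None
    out_dir: str = "protomap_out"
    panel_file: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params_raw = raw.pop("params", {})
        qc = QCThresholds(**params_raw.pop("qc", {}))
        var = VariableGeneParams(**params_raw.pop("var_genes", {}))
        params = PipelineParams(qc=qc, var_genes=var, **params_raw)
        return cls(params=params, **raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages: list[str]
    artifacts: dict[str, dict]
    started: float
    finished: float = 0.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the file-based pipeline and write artifacts + manifest."""
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.params.seed,
        stages=[],
        artifacts={},
        started=time.time(),
    )

    def record(stage: str, name: str, path) -> None:
        if stage not in manifest.stages:
            manifest.stages.append(stage)
        manifest.artifacts[name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "read"
    try:
        counts = pio.read_counts(
            config.counts_path,
            config.genes_path,
            config.barcodes_path,
            config.metadata_path,
        )
        stage = "pipeline"
        result = cluster_cells(counts, config.params)

        stage = "write"
        if result.qc_report is not None:
            qc_path = out / "qc_report.json"
            qc_path.write_text(json.dumps(result.qc_report.to_dict(), indent=2))
            record("qc", "qc_report", qc_path)

        emb_path = out / "embedding.tsv"
        pd.DataFrame(
            result.embedding.coordinates,
            columns=[f"PC{i + 1}" for i in range(result.embedding.coordinates.shape[1])],
        ).assign(barcode=result.counts.barcodes).to_csv(emb_path, sep="\t", index=False)
        record("reduce", "embedding", emb_path)

        var_path = out / "variance.json"
        var_path.write_text(
            json.dumps(
                {
                    "component_variances": result.embedding.component_variances.tolist(),
                    "n_significant": result.embedding.n_significant,
                    "variable_genes": result.variable_genes,
                },
                indent=2,
            )
        )
        record("reduce", "variance", var_path)

        labels_path = out / "labels.tsv"
        pd.DataFrame(
            {"barcode": result.counts.barcodes, "cluster": result.labels.labels}
        ).to_csv(labels_path, sep="\t", index=False)
        record("cluster", "labels", labels_path)

        stage = "markers"
        table = wilcoxon_markers(
            result.logmat,
            result.labels.labels,
            min_frac_in=config.params.marker_min_frac_in,
            min_log2fc=config.params.marker_min_log2fc,
        )
        markers_path = out / "markers.tsv"
        table.to_csv(markers_path, sep="\t", index=False)
        record("markers", "markers", markers_path)

        stage = "annotate"
        panels = load_panels(config.panel_file)
        calls = annotate_clusters(table, panels)
        ann_path = out / "annotations.json"
        ann_path.write_text(json.dumps({str(k): v for k, v in calls.items()}, indent=2))
        record("annotate", "annotations", ann_path)

        manifest.finished = time.time()
        manifest_path = out / "manifest.json"
        manifest_path.write_text(manifest.to_json())
        return manifest
    except Exception as exc:
        partial = out / "manifest.partial.json"
        manifest.finished = time.time()
        partial.write_text(manifest.to_json())
        raise ValidationError(f"pipeline failed at stage {stage!r}: {exc}") from exc
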