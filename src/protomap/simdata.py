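"""Synthetic scRNA-seq data with known ground truth.

The generator produces sparse count matrices with the statistical structure
the downstream pipeline assumes: multiple capture batches with multiplicative
per-gene effects, discrete cell-type expression programs, optional continuous
gradients between program pairs, a stage-dependent cell-type composition,
mitochondrial genes with a controlled count share, lognormal library sizes,
and spliced/unspliced layers.

Counts are Poisson conditional on lognormal size and batch factors, which
yields overdispersed marginals with few parameters. Two RNG streams are
derived from the seed: one for structure (cell-type / stage / batch
assignment, gradient positions, program construction) and one for noise
(factors and counts), so the planted structure is stable across noise
replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CountMatrix, ValidationError
from . import io as pio


@dataclass
class CellTypeSpec:
    """One discrete expression program.

    ``marker_genes`` are gene indices whose baseline rate is multiplied by
    ``marker_boost``; ``mito_fraction_mean`` is the expected share of a
    cell's counts that fall on mitochondrial genes.
    """

    name: str
    baseline_mean: float = 0.1
    marker_genes: tuple[int, ...] = ()
    marker_boost: float = 8.0
    mito_fraction_mean: float = 0.05

    def validate(self, n_genes: int, mito_gene_count: int) -> None:
        if self.baseline_mean <= 0:
            raise ValidationError(f"baseline_mean must be positive for type {self.name!r}")
        if self.marker_boost <= 1:
            raise ValidationError(f"marker_boost must be > 1 for type {self.name!r}")
        if not 0 <= self.mito_fraction_mean < 1:
            raise ValidationError(
                f"mito_fraction_mean must be in [0, 1) for type {self.name!r}"
            )
        for g in self.marker_genes:
            if not (0 <= g < n_genes):
                raise ValidationError(
                    f"marker_genes index {g} out of range for type {self.name!r}"
                )
            if g < mito_gene_count:
                raise ValidationError(
                    f"marker_genes for type {self.name!r} overlap mitochondrial indices"
                )


@dataclass
class SimConfig:
    """Full description of one synthetic dataset."""

    n_cells: int = 2000
    n_genes: int = 1000
    n_batches: int = 2
    cell_types: list[CellTypeSpec] = field(default_factory=list)
    batch_effect_sd: float = 0.15
    library_size_logmean: float = np.log(5000.0)
    library_size_logsd: float = 0.35
    mito_gene_count: int = 10
    spliced_fraction: float = 0.75
    gradient_pairs: list[tuple[str, str]] = field(default_factory=list)
    # stage label -> {type name: abundance weight}; weights sum to 1 per stage
    stages: dict[str, dict[str, float]] | None = None
    seed: int = 0
    # optional recorded permutation of gene order, applied after generation
    gene_permutation: np.ndarray | None = None

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValidationError("n_cells must be positive")
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.n_batches <= 0:
            raise ValidationError("n_batches must be positive")
        if not self.cell_types:
            raise ValidationError("cell_types must be nonempty")
        if self.batch_effect_sd < 0:
            raise ValidationError("batch_effect_sd must be nonnegative")
        if self.library_size_logsd < 0:
            raise ValidationError("library_size_logsd must be nonnegative")
        if self.mito_gene_count < 0:
            raise ValidationError("mito_gene_count must be nonnegative")
        if not 0 < self.spliced_fraction <= 1:
            raise ValidationError("spliced_fraction must be in (0, 1]")
        names = [t.name for t in self.cell_types]
        if len(set(names)) != len(names):
            raise ValidationError("cell_types names must be unique")
        for t in self.cell_types:
            t.validate(self.n_genes, self.mito_gene_count)
        for a, b in self.gradient_pairs:
            if a not in names or b not in names:
                raise ValidationError(f"gradient_pairs references unknown type ({a}, {b})")
        if self.stages is not None:
            for stage, weights in self.stages.items():
                unknown = set(weights) - set(names)
                if unknown:
                    raise ValidationError(f"stages[{stage!r}] references unknown types {unknown}")
                total = sum(weights.values())
                if not np.isclose(total, 1.0):
                    raise ValidationError(
                        f"stages[{stage!r}] abundance weights sum to {total}, expected 1"
                    )
        if self.gene_permutation is not None:
            perm = np.asarray(self.gene_permutation)
            if sorted(perm.tolist()) != list(range(self.n_genes)):
                raise ValidationError("gene_permutation must be a permutation of gene indices")


@dataclass
class GroundTruth:
    """Planted per-cell labels and cross-dataset correspondences."""

    cell_type_labels: np.ndarray
    batch_labels: np.ndarray
    stage_labels: np.ndarray
    gradient_position: np.ndarray  # NaN where not a gradient cell
    planted_correspondence: dict[str, str] | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "cell_type_labels": self.cell_type_labels.tolist(),
                "batch_labels": self.batch_labels.tolist(),
                "stage_labels": self.stage_labels.tolist(),
                "gradient_position": [
                    None if np.isnan(x) else float(x) for x in self.gradient_position
                ],
                "planted_correspondence": self.planted_correspondence,
            },
            indent=2,
        )


def _rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Structure and noise streams, independently derived from the seed."""
    ss = np.random.SeedSequence(seed)
    structure, noise = ss.spawn(2)
    return np.random.default_rng(structure), np.random.default_rng(noise)


def _gene_names(config: SimConfig) -> np.ndarray:
    names = [f"MT-{i + 1}" for i in range(config.mito_gene_count)]
    names += [f"G{i:05d}" for i in range(config.mito_gene_count, config.n_genes)]
    return np.asarray(names, dtype=object)


def _type_programs(config: SimConfig) -> dict[str, np.ndarray]:
    """Per-type expected expression rate per gene (before size/batch factors).

    Mitochondrial rates are set so the expected mitochondrial count share
    equals the type's ``mito_fraction_mean``.
    """
    programs = {}
    nm = config.mito_gene_count
    for t in config.cell_types:
        lam = np.full(config.n_genes, t.baseline_mean, dtype=np.float64)
        if t.marker_genes:
            lam[list(t.marker_genes)] *= t.marker_boost
        if nm:
            non_mito_total = lam[nm:].sum()
            m = t.mito_fraction_mean
            mito_total = m / (1.0 - m) * non_mito_total if m > 0 else 0.0
            lam[:nm] = mito_total / nm
        programs[t.name] = lam
    return programs


def _assign_cells(config: SimConfig, rng: np.random.Generator):
    """Structure draws: stage, type, batch, gradient position per cell."""
    type_names = [t.name for t in config.cell_types]
    stages = config.stages or {"S1": {n: 1.0 / len(type_names) for n in type_names}}
    stage_names = list(stages)
    # cells split evenly across stages (remainder to the earliest stages)
    per_stage = np.full(len(stage_names), config.n_cells // len(stage_names))
    per_stage[: config.n_cells % len(stage_names)] += 1

    stage_labels = np.concatenate(
        [np.repeat(s, k) for s, k in zip(stage_names, per_stage)]
    ).astype(object)
    type_labels = np.empty(config.n_cells, dtype=object)
    pos = 0
    for s, k in zip(stage_names, per_stage):
        weights = stages[s]
        names = list(weights)
        p = np.asarray([weights[n] for n in names], dtype=float)
        type_labels[pos : pos + k] = rng.choice(names, size=k, p=p / p.sum())
        pos += k

    batch_labels = np.asarray(
        [f"batch{b + 1}" for b in rng.integers(0, config.n_batches, config.n_cells)],
        dtype=object,
    )

    gradient_position = np.full(config.n_cells, np.nan)
    pair_of = {}
    for a, b in config.gradient_pairs:
        pair_of[a] = (a, b)
        pair_of[b] = (a, b)
    for i in range(config.n_cells):
        if type_labels[i] in pair_of:
            a, b = pair_of[type_labels[i]]
            u = rng.uniform()
            gradient_position[i] = u
            # label by nearest endpoint, so abundance splits evenly
            type_labels[i] = a if u < 0.5 else b
    return type_labels, batch_labels, stage_labels, gradient_position


def _generate_counts(
    config: SimConfig,
    programs: dict[str, np.ndarray],
    type_labels,
    batch_labels,
    gradient_position,
    noise_rng: np.random.Generator,
) -> CountMatrix:
    n_genes, n_cells = config.n_genes, config.n_cells
    # per-gene, per-batch lognormal factors with unit mean
    sd = config.batch_effect_sd
    batch_factors = np.exp(
        noise_rng.normal(-0.5 * sd**2, sd, size=(n_genes, config.n_batches))
    )
    batch_index = {f"batch{b + 1}": b for b in range(config.n_batches)}

    # lognormal library-size factors scaled so the expected total matches
    # the configured library size
    size_raw = np.exp(
        noise_rng.normal(config.library_size_logmean, config.library_size_logsd, n_cells)
    )

    pair_of = {}
    for a, b in config.gradient_pairs:
        pair_of[a] = (a, b)
        pair_of[b] = (a, b)

    lam = np.empty((n_genes, n_cells), dtype=np.float64)
    for i in range(n_cells):
        t = type_labels[i]
        if t in pair_of and not np.isnan(gradient_position[i]):
            a, b = pair_of[t]
            u = gradient_position[i]
            lam[:, i] = (1.0 - u) * programs[a] + u * programs[b]
        else:
            lam[:, i] = programs[t]

    cols = np.asarray([batch_index[b] for b in batch_labels])
    mean = lam * batch_factors[:, cols]
    # normalize each cell's program so the size factor is its expected total
    mean *= size_raw / mean.sum(axis=0)

    counts = noise_rng.poisson(mean)
    spliced = noise_rng.binomial(counts, config.spliced_fraction)
    unspliced = counts - spliced

    perm = config.gene_permutation
    gene_names = _gene_names(config)
    if perm is not None:
        perm = np.asarray(perm)
        counts, spliced, unspliced = counts[perm], spliced[perm], unspliced[perm]
        gene_names = gene_names[perm]

    barcodes = np.asarray([f"cell{i:06d}" for i in range(n_cells)], dtype=object)
    metadata = pd.DataFrame({"barcode": barcodes, "batch": batch_labels})
    return CountMatrix(
        sp.csc_matrix(counts),
        gene_names,
        barcodes,
        metadata=metadata,
        layers={"spliced": sp.csc_matrix(spliced), "unspliced": sp.csc_matrix(unspliced)},
    )


def generate_dataset(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Generate one synthetic dataset and its ground truth.

    Counts follow ``Poisson(s_i * b_{g,batch(i)} * lambda_{g,type(i)})`` with
    lognormal size factors ``s_i`` and per-gene lognormal batch factors ``b``;
    gradient cells interpolate the endpoint programs linearly. Identical
    seeds give identical output.
    """
    config.validate()
    structure_rng, noise_rng = _rngs(config.seed)
    programs = _type_programs(config)
    type_labels, batch_labels, stage_labels, gradient_position = _assign_cells(
        config, structure_rng
    )
    cm = _generate_counts(
        config, programs, type_labels, batch_labels, gradient_position, noise_rng
    )
    cm.metadata["stage"] = stage_labels
    cm.metadata["type_true"] = type_labels
    cm.metadata["gradient_position"] = gradient_position
    truth = GroundTruth(
        cell_type_labels=np.asarray(type_labels, dtype=object),
        batch_labels=batch_labels,
        stage_labels=stage_labels,
        gradient_position=gradient_position,
    )
    return cm, truth


def generate_paired_dataset(
    config: SimConfig, shared_types: list[str], divergence: float
) -> tuple[CountMatrix, CountMatrix, GroundTruth]:
    """Generate two datasets, B reusing A's programs for ``shared_types``.

    Shared programs are perturbed per gene by a lognormal factor of
    log-sd ``divergence``; non-shared types are replaced by novel programs
    (fresh random marker sets). ``planted_correspondence`` maps each shared
    type to itself; gene identifiers are common to both datasets.
    """
    config.validate()
    if divergence < 0:
        raise ValidationError("divergence must be nonnegative")
    names = [t.name for t in config.cell_types]
    if not shared_types:
        raise ValidationError("shared_types must be nonempty")
    unknown = set(shared_types) - set(names)
    if unknown:
        raise ValidationError(f"shared_types not in config cell types: {unknown}")

    cm_a, truth_a = generate_dataset(config)

    # derive an independent seed for dataset B from the config seed
    ss = np.random.SeedSequence(config.seed).spawn(3)[2]
    b_rng = np.random.default_rng(ss)
    b_seed = int(b_rng.integers(0, 2**31 - 1))

    programs_a = _type_programs(config)
    b_types: list[CellTypeSpec] = []
    perturbed: dict[str, np.ndarray] = {}
    n_marker = max((len(t.marker_genes) for t in config.cell_types), default=0)
    for t in config.cell_types:
        if t.name in shared_types:
            factor = np.exp(b_rng.normal(-0.5 * divergence**2, divergence, config.n_genes))
            lam = programs_a[t.name] * factor
            perturbed[t.name] = lam
            b_types.append(t)
        else:
            novel = b_rng.choice(
                np.arange(config.mito_gene_count, config.n_genes),
                size=max(n_marker, 1),
                replace=False,
            )
            b_types.append(
                CellTypeSpec(
                    name=f"{t.name}_novel",
                    baseline_mean=t.baseline_mean,
                    marker_genes=tuple(int(g) for g in novel),
                    marker_boost=t.marker_boost,
                    mito_fraction_mean=t.mito_fraction_mean,
                )
            )

    stages_b = None
    if config.stages is not None:
        rename = {t.name: bt.name for t, bt in zip(config.cell_types, b_types)}
        stages_b = {
            s: {rename[n]: w for n, w in weights.items()}
            for s, weights in config.stages.items()
        }
    config_b = SimConfig(
        n_cells=config.n_cells,
        n_genes=config.n_genes,
        n_batches=config.n_batches,
        cell_types=b_types,
        batch_effect_sd=config.batch_effect_sd,
        library_size_logmean=config.library_size_logmean,
        library_size_logsd=config.library_size_logsd,
        mito_gene_count=config.mito_gene_count,
        spliced_fraction=config.spliced_fraction,
        gradient_pairs=[],
        stages=stages_b,
        seed=b_seed,
    )

    # generate B, substituting the perturbed shared programs
    config_b.validate()
    structure_rng, noise_rng = _rngs(config_b.seed)
    programs_b = _type_programs(config_b)
    for name, lam in perturbed.items():
        lam = lam.copy()
        # keep the mito share of the original spec
        nm = config.mito_gene_count
        t = next(t for t in config.cell_types if t.name == name)
        if nm:
            m = t.mito_fraction_mean
            non_mito_total = lam[nm:].sum()
            lam[:nm] = (m / (1.0 - m) * non_mito_total if m > 0 else 0.0) / nm
        programs_b[name] = lam
    tl, bl, sl, gp = _assign_cells(config_b, structure_rng)
    cm_b = _generate_counts(config_b, programs_b, tl, bl, gp, noise_rng)
    cm_b.metadata["stage"] = sl
    cm_b.metadata["type_true"] = tl
    cm_b.metadata["gradient_position"] = gp

    truth = GroundTruth(
        cell_type_labels=truth_a.cell_type_labels,
        batch_labels=truth_a.batch_labels,
        stage_labels=truth_a.stage_labels,
        gradient_position=truth_a.gradient_position,
        planted_correspondence={t: t for t in shared_types},
    )
    return cm_a, cm_b, truth


def well_separated_config(
    n_cells: int = 5000,
    n_genes: int = 2000,
    n_types: int = 6,
    n_batches: int = 3,
    markers_per_type: int = 40,
    marker_boost: float = 8.0,
    seed: int = 0,
) -> SimConfig:
    """Reference configuration: discrete, well-separated cell types.

    Disjoint marker sets are drawn from the non-mitochondrial genes with a
    structure RNG derived from the seed; library depth (median ~3,000
    counts over 2,000 genes) is deep enough that cells clear the standard
    500-detected-genes QC filter.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    mito = 10
    pool = rng.permutation(np.arange(mito, n_genes))
    if n_types * markers_per_type > len(pool):
        raise ValidationError("not enough genes for disjoint marker sets")
    types = [
        CellTypeSpec(
            name=f"type{t}",
            marker_genes=tuple(
                int(g) for g in pool[t * markers_per_type : (t + 1) * markers_per_type]
            ),
            marker_boost=marker_boost,
        )
        for t in range(n_types)
    ]
    return SimConfig(
        n_cells=n_cells,
        n_genes=n_genes,
        n_batches=n_batches,
        cell_types=types,
        mito_gene_count=mito,
        library_size_logmean=float(np.log(3000.0)),
        seed=seed,
    )


def write_dataset(cm: CountMatrix, truth: GroundTruth, out_prefix) -> dict[str, str]:
    """Write the dataset as MTX + TSV sidecars and the ground truth as JSON."""
    paths = pio.write_counts(cm, out_prefix)
    out_prefix = Path(out_prefix)
    gt = out_prefix.parent / (out_prefix.name + ".ground_truth.json")
    gt.write_text(truth.to_json())
    paths["ground_truth"] = str(gt)
    return paths
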