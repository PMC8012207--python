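"""Generative-model contracts of the synthetic data module."""

import numpy as np
import pytest

import protomap as pm
from protomap.core import ValidationError
from protomap.simdata import CellTypeSpec, SimConfig


def _one_type_config(**kwargs):
    defaults = dict(
        n_cells=400,
        n_genes=300,
        n_batches=1,
        cell_types=[CellTypeSpec(name="t0", marker_genes=(20, 21, 22))],
        mito_gene_count=5,
        library_size_logmean=np.log(2000.0),
        seed=3,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


def test_no_noise_case_gives_identical_expected_means():
    """With zero batch and size-factor noise, every cell shares one mean vector."""
    config = _one_type_config(batch_effect_sd=0.0, library_size_logsd=0.0, n_cells=3000)
    cm, _ = pm.generate_dataset(config)
    totals = cm.cell_totals()
    # all totals are Poisson draws around the same library size
    assert abs(totals.mean() - 2000.0) < 5 * np.sqrt(2000.0 / 3000)
    # per-gene sample means across cells agree with a single shared profile:
    # marker genes ~8x the baseline genes
    gm = np.asarray(cm.counts.mean(axis=1)).ravel()
    baseline = np.median(gm[5:])
    for g in (20, 21, 22):
        assert gm[g] == pytest.approx(8.0 * baseline, rel=0.15)


def test_same_seed_is_bit_identical():
    config = _one_type_config()
    a, _ = pm.generate_dataset(config)
    b, _ = pm.generate_dataset(_one_type_config())
    assert (a.counts != b.counts).nnz == 0
    for layer in ("spliced", "unspliced"):
        assert (a.layers[layer] != b.layers[layer]).nnz == 0


def test_mito_fraction_matches_analytic_expectation():
    config = _one_type_config(
        n_cells=2000,
        cell_types=[CellTypeSpec(name="t0", marker_genes=(20,), mito_fraction_mean=0.05)],
    )
    cm, _ = pm.generate_dataset(config)
    mito = np.asarray(cm.counts[:5, :].sum(axis=0)).ravel()
    frac = mito / cm.cell_totals()
    assert abs(frac.mean() - 0.05) < 0.01


def test_spliced_plus_unspliced_equals_total_exactly():
    cm, _ = pm.generate_dataset(_one_type_config())
    diff = cm.layers["spliced"] + cm.layers["unspliced"] - cm.counts
    assert abs(diff).sum() == 0


def test_library_size_logmean_within_three_standard_errors():
    config = _one_type_config(n_cells=1500)
    cm, _ = pm.generate_dataset(config)
    logs = np.log(cm.cell_totals().astype(float))
    se = logs.std(ddof=1) / np.sqrt(len(logs))
    assert abs(logs.mean() - config.library_size_logmean) < 3 * se


def test_gene_permutation_gives_permuted_identical_matrices():
    config = _one_type_config()
    base, _ = pm.generate_dataset(config)
    rng = np.random.default_rng(9)
    perm = rng.permutation(config.n_genes)
    permuted, _ = pm.generate_dataset(_one_type_config(gene_permutation=perm))
    assert (base.counts[perm, :] != permuted.counts).nnz == 0
    assert list(base.gene_names[perm]) == list(permuted.gene_names)


def test_gradient_cells_interpolate_between_endpoint_programs():
    types = [
        CellTypeSpec(name="a", marker_genes=(20, 21, 22, 23)),
        CellTypeSpec(name="b", marker_genes=(40, 41, 42, 43)),
    ]
    config = _one_type_config(
        n_cells=3000, cell_types=types, gradient_pairs=[("a", "b")],
        batch_effect_sd=0.0,
    )
    cm, truth = pm.generate_dataset(config)
    assert np.isfinite(truth.gradient_position).all()
    # cells near u=0 express a's markers, near u=1 express b's
    lo = truth.gradient_position < 0.2
    hi = truth.gradient_position > 0.8
    a_marker = np.asarray(cm.counts[20:24, :].sum(axis=0)).ravel()
    b_marker = np.asarray(cm.counts[40:44, :].sum(axis=0)).ravel()
    assert a_marker[lo].mean() > 3 * a_marker[hi].mean()
    assert b_marker[hi].mean() > 3 * b_marker[lo].mean()
    # labels split roughly evenly between the endpoints
    share_a = (truth.cell_type_labels == "a").mean()
    assert 0.4 < share_a < 0.6


def test_stage_abundance_weights_control_composition():
    types = [CellTypeSpec(name="a", marker_genes=(20,)), CellTypeSpec(name="b", marker_genes=(30,))]
    stages = {"CS13": {"a": 0.9, "b": 0.1}, "CS16": {"a": 0.1, "b": 0.9}}
    config = _one_type_config(n_cells=2000, cell_types=types, stages=stages)
    _, truth = pm.generate_dataset(config)
    early = truth.stage_labels == "CS13"
    assert (truth.cell_type_labels[early] == "a").mean() > 0.8
    assert (truth.cell_type_labels[~early] == "b").mean() > 0.8


@pytest.mark.parametrize(
    "field,value,message",
    [
        ("n_cells", 0, "n_cells"),
        ("n_genes", -5, "n_genes"),
        ("batch_effect_sd", -0.1, "batch_effect_sd"),
        ("spliced_fraction", 0.0, "spliced_fraction"),
        ("mito_gene_count", -1, "mito_gene_count"),
    ],
)
def test_invalid_config_names_the_field(field, value, message):
    config = _one_type_config(**{field: value})
    with pytest.raises(ValidationError, match=message):
        pm.generate_dataset(config)


def test_invalid_cell_type_spec_rejected():
    with pytest.raises(ValidationError, match="marker_boost"):
        pm.generate_dataset(
            _one_type_config(cell_types=[CellTypeSpec(name="t", marker_boost=0.5)])
        )


def test_paired_zero_divergence_reproduces_programs():
    config = pm.simdata.well_separated_config(
        n_cells=1200, n_genes=800, n_types=4, n_batches=1, markers_per_type=25, seed=5
    )
    config.batch_effect_sd = 0.0  # isolate program identity from batch noise
    shared = [t.name for t in config.cell_types]
    cm_a, cm_b, truth = pm.generate_paired_dataset(config, shared, divergence=0.0)
    assert truth.planted_correspondence == {t: t for t in shared}
    # empirical per-type mean profiles of B match A closely
    for t in shared:
        in_a = (cm_a.metadata["type_true"] == t).to_numpy()
        in_b = (cm_b.metadata["type_true"] == t).to_numpy()
        ma = np.asarray(cm_a.counts[:, in_a].mean(axis=1)).ravel()
        mb = np.asarray(cm_b.counts[:, in_b].mean(axis=1)).ravel()
        r = np.corrcoef(ma, mb)[0, 1]
        assert r > 0.98


def test_paired_partial_sharing_bookkeeping():
    config = pm.simdata.well_separated_config(
        n_cells=600, n_genes=800, n_types=5, n_batches=1, markers_per_type=20, seed=6
    )
    shared = [t.name for t in config.cell_types[:3]]
    _, cm_b, truth = pm.generate_paired_dataset(config, shared, divergence=0.1)
    assert len(truth.planted_correspondence) == 3
    b_types = set(cm_b.metadata["type_true"])
    assert set(shared) <= b_types
    assert any(name.endswith("_novel") for name in b_types)


def test_paired_empty_shared_types_rejected():
    config = pm.simdata.well_separated_config(n_cells=200, n_genes=400, n_types=3, seed=1)
    with pytest.raises(ValidationError, match="shared_types"):
        pm.generate_paired_dataset(config, [], divergence=0.1)


def test_write_dataset_round_trip(tmp_path):
    cm, truth = pm.generate_dataset(_one_type_config(n_cells=50, n_genes=80))
    paths = pm.write_dataset(cm, truth, tmp_path / "sim")
    back = pm.read_counts(
        paths["counts"], paths["genes"], paths["barcodes"], paths["metadata"]
    )
    assert (back.counts != cm.counts).nnz == 0
    assert list(back.gene_names) == list(cm.gene_names)
    assert "spliced" in back.layers and "unspliced" in back.layers
    assert (back.layers["spliced"] != cm.layers["spliced"]).nnz == 0
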