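"""Feature selection, batch-regressed scaling and PCA.

Variable genes are selected by binned dispersion z-scores on the exp scale
(mean and variance/mean dispersion of ``2**x - 1``), genes binned into
equal-frequency mean bins and their dispersions z-scored within bin. Scaling
regresses batch out per gene (least squares on batch indicators, i.e.
group-mean centering), standardizes the residuals and clips them. The number
of informative principal components is estimated by permutation parallel
analysis: each gene's values are permuted across cells, the leading
eigenvalues recomputed, and observed eigenvalues are kept while they exceed
the permutation quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import NormalizedMatrix, ValidationError, check_labels

logger = logging.getLogger(__name__)


@dataclass
class VariableGeneParams:
    n_bins: int = 20
    dispersion_z_min: float = 0.5
    mean_min: float = 0.0125
    mean_max: float = 3.0

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if not self.mean_min < self.mean_max:
            raise ValidationError("mean_min must be < mean_max")


@dataclass
class Embedding:
    """Cells x components coordinates with per-component variances.

    ``loadings`` (components x genes) and ``mean`` allow reconstruction of
    the scaled matrix as ``coordinates @ loadings + mean``.
    """

    coordinates: np.ndarray
    component_variances: np.ndarray
    n_significant: int = 0
    loadings: np.ndarray | None = None
    mean: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.component_variances, dtype=float)
        if np.any(np.diff(v) > 1e-9 * max(1.0, abs(v[0]) if len(v) else 1.0)):
            raise ValidationError("component_variances must be nonincreasing")
        if self.n_significant > self.coordinates.shape[1]:
            raise ValidationError("n_significant exceeds number of components")

    @property
    def significant(self) -> np.ndarray:
        k = self.n_significant or self.coordinates.shape[1]
        return self.coordinates[:, :k]


def _exp_scale_stats(logmat: NormalizedMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and dispersion (variance/mean) of 2**x - 1."""
    x = logmat.values.tocsr()
    n = x.shape[1]
    expm = x.copy()
    expm.data = np.exp2(expm.data) - 1.0
    mean = np.asarray(expm.mean(axis=1)).ravel()
    sq = expm.copy()
    sq.data = sq.data**2
    var = np.asarray(sq.mean(axis=1)).ravel() - mean**2
    var *= n / max(n - 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return mean, dispersion


def select_variable_genes(
    logmat: NormalizedMatrix, params: VariableGeneParams | None = None
) -> list[str]:
    """Return variable gene names ordered by within-bin dispersion z, descending."""
    params = params or VariableGeneParams()
    params.validate()
    n_genes = logmat.n_genes
    if n_genes < params.n_bins:
        raise ValidationError(f"{n_genes} genes is fewer than n_bins={params.n_bins}")
    mean, dispersion = _exp_scale_stats(logmat)

    # equal-frequency bins by mean
    order = np.argsort(mean, kind="stable")
    bins = np.empty(n_genes, dtype=int)
    bins[order] = np.minimum(
        (np.arange(n_genes) * params.n_bins) // n_genes, params.n_bins - 1
    )
    z = np.zeros(n_genes)
    for b in range(params.n_bins):
        members = bins == b
        d = dispersion[members]
        sd = d.std(ddof=1) if members.sum() > 1 else 0.0
        if sd > 0:
            z[members] = (d - d.mean()) / sd
        # zero-variance bin: z stays 0 for its members

    # mean cutoffs are on the ln(1 + mean) scale, the convention under which
    # the default [0.0125, 3] window was established
    log_mean = np.log1p(mean)
    selected = (
        (z >= params.dispersion_z_min)
        & (log_mean >= params.mean_min)
        & (log_mean <= params.mean_max)
    )
    idx = np.flatnonzero(selected)
    idx = idx[np.argsort(-z[idx], kind="stable")]
    return [str(g) for g in logmat.gene_names[idx]]


def scale_and_regress(
    logmat: NormalizedMatrix,
    genes: list[str],
    batch_labels=None,
    clip: float = 10.0,
) -> tuple[np.ndarray, list[str]]:
    """Regress batch out per gene, standardize residuals, clip at +-clip.

    Returns a dense genes x cells array (rows follow ``genes``) plus the
    gene list actually used. Least squares on batch indicator variables with
    an intercept equals centering each gene on its batch means; a single
    batch therefore reduces to plain centering.
    """
    if batch_labels is None:
        batch_labels = logmat.batch_labels()
    batch_labels = check_labels(batch_labels, logmat.n_cells, "batch_labels")

    name_to_row = {str(g): i for i, g in enumerate(logmat.gene_names)}
    missing = [g for g in genes if g not in name_to_row]
    if missing:
        raise ValidationError(f"genes not in matrix: {missing[:5]}")
    rows = [name_to_row[g] for g in genes]
    x = np.asarray(logmat.values.tocsr()[rows, :].todense(), dtype=np.float64)

    for batch in np.unique(batch_labels):
        cols = batch_labels == batch
        x[:, cols] -= x[:, cols].mean(axis=1, keepdims=True)

    sd = x.std(axis=1, ddof=0)
    nonzero = sd > 0
    x[nonzero] /= sd[nonzero, None]
    x[~nonzero] = 0.0
    np.clip(x, -clip, clip, out=x)
    return x, list(genes)


def _pca_svd(scaled: np.ndarray, n_components: int):
    """Exact PCA of cells in gene space; deterministic sign convention."""
    x = np.asarray(scaled, dtype=np.float64).T  # cells x genes
    n_cells, n_genes = x.shape
    if n_components > min(n_cells, n_genes):
        raise ValidationError(
            f"n_components={n_components} exceeds min(cells, genes)={min(n_cells, n_genes)}"
        )
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # sign convention: largest-|loading| entry of each component is positive
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    coords = u[:, :n_components] * s[:n_components]
    variances = (s[:n_components] ** 2) / max(n_cells - 1, 1)
    return coords, variances, vt[:n_components], x.mean(axis=0)


def pca(scaled: np.ndarray, n_components: int = 50) -> Embedding:
    """Exact PCA of a scaled genes x cells matrix."""
    coords, variances, loadings, mean = _pca_svd(scaled, n_components)
    return Embedding(
        coordinates=coords,
        component_variances=variances,
        loadings=loadings,
        mean=mean,
    )


def _leading_eigenvalues(x_genes_by_cells: np.ndarray, k: int) -> np.ndarray:
    """Top-k covariance eigenvalues, via the smaller-dimension Gram matrix."""
    x = np.asarray(x_genes_by_cells, dtype=np.float64).T  # cells x genes
    n = x.shape[0]
    xc = x - x.mean(axis=0, keepdims=True)
    if xc.shape[1] <= xc.shape[0]:
        gram = xc.T @ xc
    else:
        gram = xc @ xc.T
    ev = np.linalg.eigvalsh(gram)[::-1]
    ev = np.maximum(ev, 0.0) / max(n - 1, 1)
    return ev[:k]


def significant_pcs(
    scaled: np.ndarray,
    n_components: int = 50,
    n_permutations: int = 100,
    quantile: float = 0.95,
    seed: int = 0,
) -> int:
    """Permutation parallel analysis for the number of informative PCs.

    Each gene's values are permuted across cells independently,
    ``n_permutations`` times; the observed leading eigenvalues are compared
    componentwise to the permutation quantile, and the count of leading
    observed eigenvalues exceeding it is returned (floored at 2).
    """
    if n_permutations < 10:
        logger.warning("n_permutations=%d is small; estimates will be noisy", n_permutations)
    scaled = np.asarray(scaled, dtype=np.float64)
    k = min(n_components, min(scaled.shape) - 1)
    observed = _leading_eigenvalues(scaled, k)
    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, k))
    for p in range(n_permutations):
        null[p] = _leading_eigenvalues(rng.permuted(scaled, axis=1), k)
    cutoff = np.quantile(null, quantile, axis=0)
    exceeds = observed > cutoff
    n_sig = int(np.argmin(exceeds)) if not exceeds.all() else k
    return max(n_sig, 2)


def reduce_dimensions(
    logmat: NormalizedMatrix,
    batch_labels=None,
    var_params: VariableGeneParams | None = None,
    n_components: int = 50,
    n_permutations: int = 100,
    seed: int = 0,
    clip: float = 10.0,
) -> tuple[Embedding, list[str]]:
    """Variable genes -> scale/regress -> PCA -> significant-PC count."""
    genes = select_variable_genes(logmat, var_params)
    if not genes:
        raise ValidationError("no variable genes selected")
    scaled, genes = scale_and_regress(logmat, genes, batch_labels, clip=clip)
    n_components = min(n_components, min(scaled.shape[1], len(genes)))
    emb = pca(scaled, n_components)
    emb.n_significant = min(
        significant_pcs(scaled, n_components, n_permutations, seed=seed), n_components
    )
    return emb, genes
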