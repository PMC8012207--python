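"""Pathway-program expression trajectories over developmental stage.

A program score is the per-cell mean log expression of a gene set (e.g. a
KEGG pathway). The trajectory is a degree-1 loess fit of that score on
numeric stage position (tricube kernel, nearest-neighbor span window),
evaluated on a grid spanning the observed stages only, with a pointwise
normal-approximation confidence band at configurable quantiles (default
5-95%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .core import NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class TrajectoryResult:
    stage_order: list
    stage_positions: np.ndarray
    raw_means: np.ndarray  # per-stage mean score
    grid: np.ndarray
    smooth: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    span: float
    gene_set_name: str = ""


def program_score(logmat: NormalizedMatrix, gene_set) -> np.ndarray:
    """Per-cell mean log expression over the gene set's present genes."""
    wanted = [str(g) for g in gene_set]
    name_to_row = {str(g): i for i, g in enumerate(logmat.gene_names)}
    rows = [name_to_row[g] for g in wanted if g in name_to_row]
    missing = len(wanted) - len(rows)
    if not rows:
        raise ValidationError("gene_set has no genes in the matrix")
    if missing:
        logger.info("program_score: %d/%d genes missing from matrix", missing, len(wanted))
    sub = logmat.values.tocsr()[rows, :]
    return np.asarray(sub.mean(axis=0)).ravel()


def _loess_fit_at(x0: float, x: np.ndarray, y: np.ndarray, k: int):
    """Weighted linear fit at x0; returns (fitted, ||l||^2 of smoother weights)."""
    d = np.abs(x - x0)
    idx = np.argsort(d, kind="stable")[:k]
    dmax = d[idx].max()
    if dmax == 0:
        # all window points at x0: weighted mean with equal weights
        w = np.ones(len(idx))
    else:
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-12)
    xw = x[idx]
    # weighted least squares on [1, (x - x0)]; fitted value is the intercept
    sw = w.sum()
    xm = (w * xw).sum() / sw
    dx = xw - xm
    sxx = (w * dx**2).sum()
    if sxx <= 1e-30:
        l = w / sw
    else:
        l = w * (1.0 / sw + (x0 - xm) * dx / sxx)
    fitted = float((l * y[idx]).sum())
    return fitted, float((l**2).sum())


def loess_trajectory(
    scores,
    stage_labels,
    span: float = 0.75,
    grid_points: int = 100,
    conf: tuple[float, float] = (0.05, 0.95),
    stage_positions: dict | None = None,
    gene_set_name: str = "",
) -> TrajectoryResult:
    """Loess smooth of program scores over stage, with a confidence band.

    Stage labels map to consecutive integers in sorted order unless
    ``stage_positions`` overrides the numeric placement. The band is
    ``smooth + z_q * sigma * ||l(x)||`` at the requested quantiles, with
    sigma estimated from the residuals at the observed stages.
    """
    scores = np.asarray(scores, dtype=np.float64)
    stage_labels = np.asarray(stage_labels)
    if scores.shape != stage_labels.shape:
        raise ValidationError("scores and stage_labels must align")
    stages = sorted(set(stage_labels.tolist()))
    if len(stages) < 3:
        raise ValidationError(f"need >= 3 distinct stages, got {len(stages)}")
    if stage_positions is None:
        stage_positions = {s: float(i) for i, s in enumerate(stages)}
    x = np.asarray([stage_positions[s] for s in stage_labels], dtype=np.float64)
    n = len(x)
    k = int(np.ceil(span * n))
    if k < 3:
        raise ValidationError(
            f"span={span} gives windows of {k} < 3 points (n={n})"
        )

    raw_means = np.asarray([scores[stage_labels == s].mean() for s in stages])
    grid = np.linspace(x.min(), x.max(), grid_points)

    smooth = np.empty(grid_points)
    lnorm2 = np.empty(grid_points)
    for i, x0 in enumerate(grid):
        smooth[i], lnorm2[i] = _loess_fit_at(float(x0), x, scores, k)

    # residual variance from fits at the (few) unique stage positions
    fitted_at = {}
    for s in stages:
        fitted_at[s], _ = _loess_fit_at(stage_positions[s], x, scores, k)
    resid = scores - np.asarray([fitted_at[s] for s in stage_labels])
    dof = max(n - 2 * len(stages), 1)
    sigma2 = float((resid**2).sum()) / dof

    z_low = scipy.stats.norm.ppf(conf[0])
    z_high = scipy.stats.norm.ppf(conf[1])
    se = np.sqrt(sigma2 * lnorm2)
    band_low = smooth + z_low * se
    band_high = smooth + z_high * se
    return TrajectoryResult(
        stage_order=stages,
        stage_positions=np.asarray([stage_positions[s] for s in stages]),
        raw_means=raw_means,
        grid=grid,
        smooth=smooth,
        band_low=band_low,
        band_high=band_high,
        span=span,
        gene_set_name=gene_set_name,
    )
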