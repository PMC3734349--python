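"""Simplified GLM functional localizer.

Defines ROI masks as the voxels with a significant positive BOLD
response to the task: a least-squares fit of a boxcar convolved with
the canonical (double-gamma) hemodynamic response function plus
constant and linear-drift regressors, a one-sided t statistic per
voxel, and a Bonferroni-corrected threshold.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import t as t_dist

from .data import COND_AL, COND_AR, ExperimentDesign

__all__ = ["canonical_hrf", "task_regressor", "glm_localizer"]


def canonical_hrf(TR: float, duration_s: float = 32.0) -> np.ndarray:
    """Double-gamma HRF sampled at TR (peak 6 s, undershoot 16 s, ratio 6)."""
    t = np.arange(0.0, duration_s, TR)

    def gpdf(x, shape, scale=1.0):
        x = np.maximum(x, 1e-12)
        return np.exp((shape - 1) * np.log(x) - x / scale
                      - gammaln(shape) - shape * np.log(scale))

    h = gpdf(t, 6.0) - gpdf(t, 16.0) / 6.0
    return h / h.sum()


def task_regressor(design: ExperimentDesign,
                   labels=(COND_AL, COND_AR)) -> np.ndarray:
    """Boxcar over the given block labels convolved with the canonical HRF."""
    scan_labels = design.scan_condition_labels()
    box = np.isin(scan_labels, labels).astype(float)
    if not box.any():
        raise ValueError("design contains no task blocks")
    return np.convolve(box, canonical_hrf(design.TR))[: design.n_scans]


def glm_localizer(
    voxel_series: np.ndarray,
    design: ExperimentDesign,
    alpha: float = 0.05,
    extra_regressors: np.ndarray | None = None,
) -> np.ndarray:
    """Binary mask of voxels with a significant positive task response.

    ``voxel_series`` is scans x voxels.  The threshold is Bonferroni
    corrected over voxels (one-sided test at level ``alpha``).
    """
    Y = np.atleast_2d(np.asarray(voxel_series, dtype=float))
    n, v = Y.shape
    if n != design.n_scans:
        raise ValueError(
            f"voxel series has {n} scans but design covers {design.n_scans}"
        )
    reg = task_regressor(design)
    cols = [reg, np.ones(n), np.linspace(-1.0, 1.0, n)]
    if extra_regressors is not None:
        cols.extend(np.atleast_2d(extra_regressors.T))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[0, 0], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta[0] / se, 0.0)
    pvals = t_dist.sf(tvals, dof)
    return pvals < (alpha / v)
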