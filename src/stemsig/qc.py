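"""Dataset quality control via the PCA separation score.

A dataset is usable only when its control and test samples separate along a
leading principal component.  The score is the fraction of samples on the
correct side of the best single-axis threshold split over the first few
principal components: 1.0 means a clean bipartition, 0.75 on a 12-sample
dataset means 3 samples sit on the wrong side.  Datasets below a minimum
score (default 0.75, inclusive) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io import ExpressionDataset


@dataclass
class SeparationReport:
    """Result of :func:`pca_separation_score` for one dataset.

    ``pca_score`` = 1 - n_misplaced / n_samples, always >= 0.5 because both
    group-to-side assignments are tried.  ``axis_used`` is the 0-based index
    of the principal component achieving the minimum; ``threshold`` the
    projection value of the best split.
    """

    name: str
    pca_score: float
    n_misplaced: int
    axis_used: int
    threshold: float


def _sample_projections(dataset: ExpressionDataset, n_axes: int) -> np.ndarray:
    """Project samples onto the first ``n_axes`` principal components.

    Genes are centered but not scaled, preserving the variance weighting
    typical of expression PCA.  Returns an array of shape (n_axes_eff, n_samples).
    """
    x = dataset.values - dataset.values.mean(axis=1, keepdims=True)
    if not np.any(np.abs(x) > 0):
        raise ValueError(f"{dataset.name}: zero total variance; PCA undefined")
    # SVD of the gene-centered matrix; sample scores are s_a * Vt[a].
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > tol
    proj = (s[keep, None] * vt[keep])
    return proj[: min(n_axes, proj.shape[0])]


def best_split_misplaced(projection: np.ndarray, is_control: np.ndarray) -> tuple[int, float]:
    """Minimum misplaced count over all threshold splits of one axis.

    Thresholds are evaluated at midpoints between distinct consecutive
    projected values plus the two extremes; both group-to-side assignments
    are considered.  Returns ``(n_misplaced, threshold)``.
    """
    order = np.argsort(projection, kind="stable")
    vals = projection[order]
    ctrl = is_control[order]
    uniq = np.unique(vals)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    span = max(uniq[-1] - uniq[0], 1.0)
    thresholds = np.concatenate(([uniq[0] - span], mids, [uniq[-1] + span]))
    n = len(vals)
    best = (n + 1, np.nan)
    for t in thresholds:
        below = vals < t
        # assignment A: control below, test above
        mis = int(np.sum(ctrl & ~below) + np.sum(~ctrl & below))
        mis = min(mis, n - mis)  # assignment B is the complement
        if mis < best[0]:
            best = (mis, float(t))
    return best


def pca_separation_score(dataset: ExpressionDataset, n_axes: int = 2) -> SeparationReport:
    """Compute the PCA separation score of a control-vs-test dataset.

    For each of the first ``n_axes`` principal components the samples'
    projections are scanned over all thresholds and both group-to-side
    assignments; the split with the globally fewest misplaced samples wins
    (ties resolved toward the lower axis index).
    """
    if len(dataset.control_ids) < 2 or len(dataset.test_ids) < 2:
        raise ValueError(f"{dataset.name}: need >=2 samples per group for a PCA score")
    if len(dataset.genes) < 2:
        raise ValueError(f"{dataset.name}: need >=2 genes")
    proj = _sample_projections(dataset, n_axes)
    is_control = dataset.is_control()
    n = dataset.n_samples
    best_mis, best_axis, best_thr = n + 1, -1, np.nan
    for axis in range(proj.shape[0]):
        mis, thr = best_split_misplaced(proj[axis], is_control)
        if mis < best_mis:
            best_mis, best_axis, best_thr = mis, axis, thr
    return SeparationReport(
        name=dataset.name,
        pca_score=1.0 - best_mis / n,
        n_misplaced=best_mis,
        axis_used=best_axis,
        threshold=best_thr,
    )


def gate_datasets(
    reports: Iterable[SeparationReport], min_score: float = 0.75
) -> tuple[list[SeparationReport], list[SeparationReport]]:
    """Partition reports into (accepted, rejected); the bound is inclusive,
    so a score of exactly ``min_score`` is accepted."""
    accepted, rejected = [], []
    for report in reports:
        (accepted if report.pca_score >= min_score else rejected).append(report)
    return accepted, rejected
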