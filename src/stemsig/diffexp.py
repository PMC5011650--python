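"""Per-gene contrast statistics and DEG selection (the individual-gene
representation of a dataset).

Each gene gets a log2 ratio (mean test minus mean control), a pooled-variance
two-sample t statistic, a two-sided p-value and a Benjamini-Hochberg FDR.
DEGs are genes passing FDR < 0.05 and fold change > 2 (strict inequalities,
fold change = 2^|log2 ratio|).  An optional moderated t shrinks per-gene
variances toward their median with a fixed prior weight; it is off by
default because the downstream stages depend on the thresholds, not on the
variance model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset


@dataclass
class DifferentialResult:
    """Per-gene statistics for one contrast; ``table`` is indexed by gene
    with columns log2_ratio, t_stat, p_value, fdr, is_deg."""

    name: str
    table: pd.DataFrame


def compute_contrast(
    dataset: ExpressionDataset,
    fdr_max: float = 0.05,
    fc_min: float = 2.0,
    moderated: bool = False,
    prior_df: float = 4.0,
) -> DifferentialResult:
    """Pooled-variance Student t per gene, BH-adjusted over all genes.

    Genes with zero pooled variance get p = 1 when their log2 ratio is also
    zero; otherwise their variance is floored at the smallest positive
    pooled variance observed, so a perfectly reproducible shift is still
    called significant.
    """
    ctrl, test = dataset.control_values, dataset.test_values
    n1, n2 = ctrl.shape[1], test.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"{dataset.name}: a single-sample arm cannot support a t-test; "
            "use fold-change-only selection"
        )
    m1, m2 = ctrl.mean(axis=1), test.mean(axis=1)
    log2_ratio = m2 - m1
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * ctrl.var(axis=1, ddof=1) + (n2 - 1) * test.var(axis=1, ddof=1)) / df
    if moderated:
        s2_prior = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 0.0
        s2 = (prior_df * s2_prior + df * s2) / (prior_df + df)
        df = df + prior_df
    positive = s2[s2 > 0]
    floor = positive.min() if positive.size else np.nan
    s2_eff = np.where(s2 > 0, s2, floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_eff * (1.0 / n1 + 1.0 / n2))
        t_stat = np.where(se > 0, log2_ratio / se, 0.0)
    p_value = 2.0 * stats.t.sf(np.abs(t_stat), df)
    # zero pooled variance and zero ratio: genuinely no evidence either way
    degenerate = (s2 <= 0) & (log2_ratio == 0)
    p_value = np.where(degenerate, 1.0, p_value)
    t_stat = np.where(degenerate, 0.0, t_stat)
    fdr = stats.false_discovery_control(p_value, method="bh")
    table = pd.DataFrame(
        {
            "log2_ratio": log2_ratio,
            "t_stat": t_stat,
            "p_value": p_value,
            "fdr": fdr,
        },
        index=pd.Index(dataset.genes, name="gene"),
    )
    table["is_deg"] = (table["fdr"] < fdr_max) & (2.0 ** table["log2_ratio"].abs() > fc_min)
    return DifferentialResult(name=dataset.name, table=table)


def select_degs(
    result: DifferentialResult, fdr_max: float = 0.05, fc_min: float = 2.0
) -> frozenset[str]:
    """Genes with fdr < fdr_max and 2^|log2_ratio| > fc_min, both strict."""
    if fdr_max <= 0 or fc_min <= 0:
        raise ValueError("thresholds must be positive")
    t = result.table
    mask = (t["fdr"] < fdr_max) & (2.0 ** t["log2_ratio"].abs() > fc_min)
    return frozenset(t.index[mask])


def deg_overlap_matrix(deg_sets: dict[str, frozenset[str]]) -> pd.DataFrame:
    """Asymmetric DEG overlap matrix.

    ``M[i, j] = |D_i & D_j| / |D_i|`` - the denominator is the row dataset's
    DEG set, so each pair appears once per denominator and the conservation
    identity ``M[i, j] * |D_i| = |D_i & D_j|`` holds exactly.  The diagonal
    is 1.  Rows/columns of empty DEG sets are reported as NaN (undefined),
    never as zero.
    """
    names = list(deg_sets)
    n = len(names)
    matrix = np.full((n, n), np.nan)
    for i, a in enumerate(names):
        da = deg_sets[a]
        if not da:
            continue
        for j, b in enumerate(names):
            db = deg_sets[b]
            if not db:
                continue
            matrix[i, j] = len(da & db) / len(da)
    return pd.DataFrame(matrix, index=names, columns=names)
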