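"""Build the datasets x features matrices used for classification.

Signatures are first filtered by overlap size against every dataset's gene
universe (default 10-200 genes, inclusive, across all platforms).  Features
are then selected either by cross-dataset significance (GSEA: nominal
p < 0.05 in at least ``min_datasets`` datasets; PAGE/GAGE: FDR below a
threshold in at least one dataset) or, for the individual-gene
representation, by highest variance of the log2 ratio across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SignatureCollection

logger = logging.getLogger(__name__)


@dataclass
class ProfileMatrix:
    """Datasets (rows) x features (columns) matrix of NES values (gene-set
    mode) or log2 ratios (individual-gene mode)."""

    values: pd.DataFrame
    mode: str  # "gsa" or "iga"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("row/column names must be unique")


def filter_signatures_by_overlap(
    collection: SignatureCollection,
    universes: Mapping[str, Sequence[str]],
    min_n: int = 10,
    max_n: int = 200,
) -> SignatureCollection:
    """Retain a signature only when its overlap with EVERY dataset's gene
    universe has between ``min_n`` and ``max_n`` genes (inclusive)."""
    if not universes:
        raise ValueError("need at least one gene universe")
    universe_sets = {name: set(u) for name, u in universes.items()}
    kept = {}
    for name, genes in collection:
        if all(min_n <= len(genes & u) <= max_n for u in universe_sets.values()):
            kept[name] = genes
    return SignatureCollection(kept, collection.source_description)


def select_signatures_gsea(
    profiles: Mapping[str, pd.DataFrame],
    p_max: float = 0.05,
    min_datasets: int = 10,
) -> list[str]:
    """Signatures with nominal p < ``p_max`` in at least ``min_datasets``
    datasets (inclusive count)."""
    counts: dict[str, int] = {}
    for frame in profiles.values():
        significant = frame.index[frame["p_nominal"] < p_max]
        for sig in significant:
            counts[sig] = counts.get(sig, 0) + 1
    return sorted(sig for sig, c in counts.items() if c >= min_datasets)


def select_signatures_by_fdr(
    profiles: Mapping[str, pd.DataFrame],
    fdr_max: float,
    min_datasets: int = 1,
) -> list[str]:
    """Signatures with per-dataset BH FDR strictly below ``fdr_max`` in at
    least ``min_datasets`` datasets (default: one)."""
    counts: dict[str, int] = {}
    for frame in profiles.values():
        passing = frame.index[frame["fdr"] < fdr_max]
        for sig in passing:
            counts[sig] = counts.get(sig, 0) + 1
    return sorted(sig for sig, c in counts.items() if c >= min_datasets)


def select_high_variance_genes(
    log2_ratio_matrix: pd.DataFrame, k: int = 152
) -> list[str]:
    """Top ``k`` genes by sample variance of the log2 ratio across datasets
    (genes x datasets input); ties broken lexicographically."""
    if k > log2_ratio_matrix.shape[0]:
        raise ValueError(f"k={k} exceeds the {log2_ratio_matrix.shape[0]} available genes")
    variance = log2_ratio_matrix.var(axis=1, ddof=1)
    order = sorted(variance.index, key=lambda g: (-variance[g], g))
    return order[:k]


def build_profile(
    selected: Sequence[str],
    per_dataset_values: Mapping[str, pd.Series | pd.DataFrame],
    mode: str,
    value_column: str = "nes",
) -> ProfileMatrix:
    """Assemble the datasets x features matrix from per-dataset values.

    ``per_dataset_values`` maps dataset name to either a Series indexed by
    feature or a profile DataFrame carrying ``value_column``.  Features with
    an undefined value in any dataset are dropped with a warning; an empty
    selection is an error.
    """
    if not list(selected):
        raise ValueError("empty feature list")
    rows = {}
    for name, values in per_dataset_values.items():
        if isinstance(values, pd.DataFrame):
            values = values[value_column]
        rows[name] = values.reindex(selected)
    frame = pd.DataFrame(rows).T
    frame = frame.loc[:, list(selected)]
    incomplete = frame.columns[frame.isna().any(axis=0)]
    if len(incomplete):
        logger.warning("dropping %d features undefined in some dataset: %s",
                       len(incomplete), list(incomplete)[:10])
        frame = frame.drop(columns=incomplete)
    if frame.shape[1] == 0:
        raise ValueError("no feature is defined in every dataset")
    return ProfileMatrix(values=frame, mode=mode)
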