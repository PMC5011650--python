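"""One-way and two-way hierarchical clustering of profile matrices.

Distance is 1 - Pearson r (not 1 - |r|: anticorrelated profiles belong to
different clusters, matching the over-/under-represented split of a
signature heatmap); linkage is average (UPGMA) by default; trees are cut
into a configured number of clusters (default 3 datasets clusters and 3
feature clusters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import SignatureCollection
from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)


@dataclass
class GenotypeAssignment:
    """Two-way clustering result: dataset and feature cluster labels,
    dendrogram leaf orders, and the dataset-dataset correlation matrix."""

    dataset_labels: pd.Series
    feature_labels: pd.Series
    dataset_order: list[str]
    feature_order: list[str]
    dataset_correlation: pd.DataFrame
    reordered: pd.DataFrame


def pearson_matrix(profile: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Symmetric Pearson correlation matrix of the row (or column) vectors.

    Constant vectors have no defined correlation and are excluded with a
    warning rather than propagated as NaN.
    """
    data = profile if axis == "rows" else profile.T
    if data.shape[1] < 2:
        raise ValueError("need >=2 features per vector for a correlation")
    sd = data.std(axis=1, ddof=1)
    constant = sd.index[~(sd > 0)]
    if len(constant):
        logger.warning("excluding %d constant vectors from the correlation: %s",
                       len(constant), list(constant)[:10])
        data = data.drop(index=constant)
    r = np.corrcoef(data.to_numpy())
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=data.index, columns=data.index)


def _correlation_linkage(corr: pd.DataFrame, linkage: str) -> np.ndarray:
    dist = 1.0 - corr.to_numpy()
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    return hierarchy.linkage(squareform(dist, checks=False), method=linkage)


def hierarchical_cluster(
    data: pd.DataFrame,
    k: int,
    linkage: str = "average",
    precomputed_correlation: bool = False,
) -> tuple[pd.Series, list[str]]:
    """Agglomerative clustering with 1 - Pearson r distance.

    ``data`` is either an items x features profile, or (with
    ``precomputed_correlation=True``) an items x items correlation matrix.
    Returns cluster labels (1..k, relabeled in dendrogram-leaf order) and
    the leaf order.  Deterministic: scipy merges equal distances by
    smallest cluster index.
    """
    if k > data.shape[0]:
        raise ValueError(f"k={k} exceeds {data.shape[0]} items")
    corr = data if precomputed_correlation else pearson_matrix(data, axis="rows")
    z = _correlation_linkage(corr, linkage)
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    leaves = hierarchy.leaves_list(z)
    names = list(corr.index)
    order = [names[i] for i in leaves]
    # relabel so cluster 1 is the first encountered along the dendrogram
    relabel: dict[int, int] = {}
    for leaf in leaves:
        relabel.setdefault(raw[leaf], len(relabel) + 1)
    labels = pd.Series([relabel[c] for c in raw], index=names, name="cluster")
    return labels, order


def two_way_cluster(
    profile: ProfileMatrix | pd.DataFrame,
    k_rows: int = 3,
    k_cols: int = 3,
    linkage: str = "average",
) -> GenotypeAssignment:
    """Cluster datasets (rows) and features (columns) independently and
    return labels, leaf orders and the heatmap-ready reordered matrix."""
    frame = profile.values if isinstance(profile, ProfileMatrix) else profile
    if frame.isna().any().any():
        raise ValueError("profile must be complete (no missing values)")
    if frame.shape[1] == 1:
        # correlation is undefined on length-1 vectors; cluster rows on the
        # single column's values instead
        z = hierarchy.linkage(frame.to_numpy(), method=linkage)
        raw = hierarchy.fcluster(z, t=min(k_rows, frame.shape[0]), criterion="maxclust")
        leaves = hierarchy.leaves_list(z)
        names = list(frame.index)
        relabel: dict[int, int] = {}
        for leaf in leaves:
            relabel.setdefault(raw[leaf], len(relabel) + 1)
        row_labels = pd.Series([relabel[c] for c in raw], index=names, name="cluster")
        row_order = [names[i] for i in leaves]
    else:
        row_labels, row_order = hierarchical_cluster(frame, k_rows, linkage=linkage)
    if frame.shape[1] == 1:
        col_labels = pd.Series([1], index=frame.columns, name="cluster")
        col_order = list(frame.columns)
    else:
        col_labels, col_order = hierarchical_cluster(frame.T, k_cols, linkage=linkage)
    if frame.shape[1] >= 2:
        corr = pearson_matrix(frame, axis="rows")
    else:  # correlation undefined on a single feature
        corr = pd.DataFrame(np.eye(frame.shape[0]), index=frame.index, columns=frame.index)
    return GenotypeAssignment(
        dataset_labels=row_labels,
        feature_labels=col_labels,
        dataset_order=row_order,
        feature_order=col_order,
        dataset_correlation=corr,
        reordered=frame.loc[row_order, col_order],
    )


def classify_with_known_signatures(
    profiles: dict[str, pd.DataFrame],
    known: SignatureCollection,
    k_rows: int = 3,
    linkage: str = "average",
) -> GenotypeAssignment:
    """Two-way clustering on the NES profile restricted to a small set of
    known signatures (e.g. six cancer/stem-cell signatures).  All-constant
    NES columns are excluded with a warning."""
    names = list(known.signatures)
    rows = {ds: frame["nes"].reindex(names) for ds, frame in profiles.items()}
    frame = pd.DataFrame(rows).T[names]
    undefined = frame.columns[frame.isna().any(axis=0)]
    if len(undefined):
        logger.warning("excluding %d known signatures with undefined NES: %s",
                       len(undefined), list(undefined))
        frame = frame.drop(columns=undefined)
    constant = frame.columns[~(frame.std(axis=0, ddof=1) > 0)]
    if len(constant):
        logger.warning("excluding %d constant NES columns: %s", len(constant), list(constant))
        frame = frame.drop(columns=constant)
    if frame.shape[1] < 2:
        raise ValueError("fewer than 2 usable known-signature columns")
    return two_way_cluster(frame, k_rows=k_rows, k_cols=min(3, frame.shape[1]), linkage=linkage)


def dendrogram_newick(data: pd.DataFrame, linkage: str = "average",
                      precomputed_correlation: bool = False) -> str:
    """Newick text export of the clustering tree (branch lengths = merge
    heights)."""
    corr = data if precomputed_correlation else pearson_matrix(data, axis="rows")
    z = _correlation_linkage(corr, linkage)
    tree = hierarchy.to_tree(z)
    names = list(corr.index)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
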