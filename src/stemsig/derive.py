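"""Derived gene sets: cluster gene sets (CGS) and per-genotype URG/DRG.

A CGS condenses a signature cluster into genes: take the union of GSEA
leading-edge genes of every cluster signature against every dataset and keep
the genes with the highest 5% frequency of occurrence in the signatures.

URG/DRG selection for a genotype: sum each signature's -log10 nominal p over
the genotype's datasets, keep the top 5% of signatures by that sum, split
them into the all-positive-NES set (PNS) and the all-negative-NES set (NNS),
then tally leading-edge frequency within each and keep the top-5%-frequency
genes (URG from PNS, DRG from NNS).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DerivedGeneSet:
    """A CGS or URG/DRG with per-gene frequency-of-occurrence evidence.

    ``frequency[g]`` counts the contributing signatures in whose leading
    edge gene g appeared (in at least one dataset, unless incidence counting
    was requested); every member has frequency >= 1.
    """

    label: str
    genes: frozenset[str]
    frequency: dict[str, int]
    provenance: list[str] = field(default_factory=list)


@dataclass
class SignatureConsistencySets:
    """PNS/NNS split of the top summed -log p signatures of one genotype."""

    pns: list[str]
    nns: list[str]
    summed_neglogp: pd.Series
    top_signatures: list[str]


def _leading_edge_frequency(
    signatures: Sequence[str],
    profiles: Mapping[str, pd.DataFrame],
    count_incidences: bool = False,
) -> dict[str, int]:
    """Per-gene count of signatures (default) or signature x dataset
    incidences in whose leading edge the gene appears."""
    freq: dict[str, int] = {}
    for sig in signatures:
        seen: set[str] = set()
        for frame in profiles.values():
            if sig not in frame.index:
                continue
            edge = frame.loc[sig, "leading_edge"]
            if not isinstance(edge, frozenset):
                continue
            if count_incidences:
                for g in edge:
                    freq[g] = freq.get(g, 0) + 1
            else:
                seen |= edge
        if not count_incidences:
            for g in seen:
                freq[g] = freq.get(g, 0) + 1
    return freq


def _top_frequency_genes(freq: Mapping[str, int], top_frac: float) -> frozenset[str]:
    """Highest-``top_frac`` fraction of positive-frequency genes: the
    ceil(top_frac * n) highest frequencies plus all ties at the cutoff
    (frequencies are small integers; strict truncation would depend on gene
    order)."""
    if not freq:
        return frozenset()
    n_take = math.ceil(top_frac * len(freq))
    ordered = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    cutoff = ordered[n_take - 1][1]
    return frozenset(g for g, f in freq.items() if f >= cutoff)


def extract_cgs(
    cluster_signatures: Sequence[str],
    profiles: Mapping[str, pd.DataFrame],
    top_frac: float = 0.05,
    label: str = "CGS",
    count_incidences: bool = False,
) -> DerivedGeneSet:
    """Cluster gene set: top-``top_frac`` frequency genes over the union of
    the cluster signatures' leading edges across all datasets."""
    if not list(cluster_signatures):
        raise ValueError("empty signature cluster")
    freq = _leading_edge_frequency(cluster_signatures, profiles, count_incidences)
    genes = _top_frequency_genes(freq, top_frac)
    return DerivedGeneSet(
        label=label,
        genes=genes,
        frequency={g: freq[g] for g in genes},
        provenance=list(cluster_signatures),
    )


def rank_and_threshold_signatures(
    profiles: Mapping[str, pd.DataFrame],
    top_frac: float = 0.05,
    aggregate: str = "sum",
) -> SignatureConsistencySets:
    """Rank signatures by summed -log10 nominal p over a genotype's datasets
    and split the top 5% by NES sign consistency.

    ``profiles`` must hold only the genotype's own (test-condition)
    datasets.  The top floor(top_frac * N) signatures are kept (boundary
    ties broken by signature name); among them PNS holds those with
    positive NES in every dataset and NNS those all-negative.  With
    ``aggregate="product"`` the per-dataset -log p values are multiplied
    instead of summed (an equivalent ranking only when datasets number one).
    A signature missing an NES in any dataset is excluded and logged.
    """
    if aggregate not in {"sum", "product"}:
        raise ValueError("aggregate must be 'sum' or 'product'")
    frames = list(profiles.values())
    if not frames:
        raise ValueError("no profiles supplied")
    common = frames[0].index
    for frame in frames[1:]:
        common = common.intersection(frame.index)
    neglogp = pd.DataFrame(
        {ds: -np.log10(frame.loc[common, "p_nominal"]) for ds, frame in profiles.items()}
    )
    nes = pd.DataFrame({ds: frame.loc[common, "nes"] for ds, frame in profiles.items()})
    defined = neglogp.notna().all(axis=1) & nes.notna().all(axis=1)
    dropped = int((~defined).sum())
    if dropped:
        logger.info("excluding %d signatures with undefined NES/p in some dataset", dropped)
    neglogp, nes = neglogp[defined], nes[defined]
    score = neglogp.sum(axis=1) if aggregate == "sum" else neglogp.prod(axis=1)
    n_top = math.floor(top_frac * len(score))
    ordered = sorted(score.index, key=lambda s: (-score[s], s))
    top = ordered[:n_top]
    pns = [s for s in top if (nes.loc[s] > 0).all()]
    nns = [s for s in top if (nes.loc[s] < 0).all()]
    return SignatureConsistencySets(
        pns=pns, nns=nns, summed_neglogp=score.sort_values(ascending=False),
        top_signatures=top,
    )


def select_urg_drg(
    consistency: SignatureConsistencySets,
    profiles: Mapping[str, pd.DataFrame],
    top_frac: float = 0.05,
    label: str = "",
    count_incidences: bool = False,
) -> tuple[DerivedGeneSet, DerivedGeneSet]:
    """URG/DRG: top-``top_frac`` leading-edge frequency genes over the PNS
    (up-regulated) and NNS (down-regulated) signatures of one genotype.
    An empty PNS (or NNS) yields an empty URG (or DRG) with a warning."""
    sets = []
    for sig_names, tag in ((consistency.pns, "URG"), (consistency.nns, "DRG")):
        name = f"{tag}-{label}" if label else tag
        if not sig_names:
            logger.warning("%s: empty signature set; derived gene set is empty", name)
            sets.append(DerivedGeneSet(label=name, genes=frozenset(), frequency={}))
            continue
        freq = _leading_edge_frequency(sig_names, profiles, count_incidences)
        genes = _top_frequency_genes(freq, top_frac)
        sets.append(
            DerivedGeneSet(
                label=name,
                genes=genes,
                frequency={g: freq[g] for g in genes},
                provenance=list(sig_names),
            )
        )
    return sets[0], sets[1]
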