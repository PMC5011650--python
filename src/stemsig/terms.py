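"""Fisher-exact over-representation of derived gene sets in GO/KEGG-style
term collections.

For each term the 2x2 table (in-query/in-term vs their complements within
the universe) is tested one-sided for over-representation; the p-value is
the hypergeometric upper tail P(X >= overlap).  BH adjustment runs across
terms, and -log10 p is reported for side-by-side profiles.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SignatureCollection

logger = logging.getLogger(__name__)


def fisher_enrichment(
    query: Iterable[str],
    terms: SignatureCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of ``query`` in every term.

    Query genes outside the universe are dropped with a warning; term sets
    are intersected with the universe.  Returns a DataFrame indexed by term
    with columns overlap, term_size, query_size, universe_size, p_value,
    neg_log_p and fdr.  An empty query gives p = 1 everywhere.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        query &= universe
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for name, genes in terms:
        term = genes & universe
        k_term = len(term)
        overlap = len(term & query)
        if k_term == 0 or n_query == 0:
            p = 1.0
        else:
            # upper tail of Hypergeometric(N=universe, K=term, n=query)
            p = float(stats.hypergeom.sf(overlap - 1, n_universe, k_term, n_query))
        p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
        rows.append((name, overlap, k_term, n_query, n_universe, p, -np.log10(p)))
    frame = pd.DataFrame(
        rows,
        columns=["term", "overlap", "term_size", "query_size", "universe_size",
                 "p_value", "neg_log_p"],
    ).set_index("term")
    frame["fdr"] = stats.false_discovery_control(frame["p_value"].to_numpy(), method="bh")
    return frame


def compare_enrichment_profiles(
    results: Mapping[str, pd.DataFrame],
    term_subset: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Derived-sets x terms matrix of -log10 p for side-by-side reporting.

    ``results`` maps a derived-set label to its :func:`fisher_enrichment`
    output; ``term_subset`` restricts and orders the columns (default: the
    terms shared by all results, in first-result order)."""
    frames = dict(results)
    if term_subset is None:
        common = None
        for frame in frames.values():
            common = frame.index if common is None else common.intersection(frame.index)
        term_subset = list(common) if common is not None else []
    return pd.DataFrame(
        {label: frame["neg_log_p"].reindex(term_subset) for label, frame in frames.items()}
    ).T[list(term_subset)]
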