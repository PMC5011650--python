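"""Gene-set enrichment scoring of a single contrast.

Three scorers over a signature collection:

* GSEA: the weighted Kolmogorov-Smirnov-like running-sum enrichment score
  (ES), a permutation-normalized enrichment score (NES) with a nominal
  permutation p-value, and the leading-edge genes at the running-sum peak.
* PAGE: the parametric z-score ``(Sm - mu) * sqrt(m) / delta`` where mu and
  delta are the mean and standard deviation of all per-gene log2 ratios and
  Sm the signature mean.
* GAGE (simplified): per (test, control) sample pair, a two-sample t of the
  signature genes' log2 fold changes against all genes, combined across
  pairs by Stouffer's method.

The default permutation scheme draws random gene sets of the same size
(signature-label permutation), appropriate for the small arms (often 3v3)
these contrasts have; phenotype (sample-label) permutation is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionDataset, SignatureCollection

#: GSEA-style standard-deviation floor used by the signal-to-noise metric.
SD_FLOOR_FRACTION = 0.2


@dataclass
class RankedList:
    """Genes in descending order of a ranking metric, with a deterministic
    lexicographic tie-break on the gene symbol."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(self.genes) < 2:
            raise ValueError("a ranked list needs at least 2 genes")
        self.position = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)


def _floored_sd(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1, ddof=1)
    mean = values.mean(axis=1)
    floor = np.maximum(SD_FLOOR_FRACTION * np.abs(mean), SD_FLOOR_FRACTION)
    return np.maximum(sd, floor)


def signal_to_noise(dataset: ExpressionDataset) -> np.ndarray:
    """(mean_test - mean_control) / (sd_test + sd_control), each sd floored
    at max(0.2 * |group mean|, 0.2) per standard GSEA practice."""
    ctrl, test = dataset.control_values, dataset.test_values
    if ctrl.shape[1] < 2 or test.shape[1] < 2:
        raise ValueError(f"{dataset.name}: signal-to-noise needs >=2 samples per arm")
    return (test.mean(axis=1) - ctrl.mean(axis=1)) / (_floored_sd(test) + _floored_sd(ctrl))


def log2_ratios(dataset: ExpressionDataset) -> pd.Series:
    """Per-gene mean(test) - mean(control) on the log2 scale."""
    values = dataset.test_values.mean(axis=1) - dataset.control_values.mean(axis=1)
    return pd.Series(values, index=dataset.genes, name="log2_ratio")


def rank_genes(dataset: ExpressionDataset, metric: str = "signal_to_noise") -> RankedList:
    """Rank all genes by the chosen contrast metric, descending; ties broken
    by lexicographically smaller gene symbol first."""
    if metric == "signal_to_noise":
        values = signal_to_noise(dataset)
    elif metric == "log2_ratio":
        values = log2_ratios(dataset).to_numpy()
    else:
        raise ValueError(f"unknown ranking metric {metric!r}")
    genes = np.asarray(dataset.genes)
    order = np.lexsort((genes, -values))
    return RankedList(genes=list(genes[order]), metric=values[order])


def _hit_mask(ranked: RankedList, signature: frozenset[str]) -> np.ndarray:
    return np.array([g in signature for g in ranked.genes], dtype=bool)


def enrichment_score(
    ranked: RankedList, signature: frozenset[str], weight: float = 1.0
) -> tuple[float, int]:
    """Signed maximum deviation of the GSEA running sum.

    Walking the ranking, the hit curve increments ``|r_i|^weight``
    (normalized to unit total over the signature's overlap) at signature
    genes, the miss curve increments ``1/(N-m)`` elsewhere; the ES is the
    deviation of largest magnitude, with ``peak_index`` the 0-based ranking
    position first attaining it.
    """
    hits = _hit_mask(ranked, signature)
    n = len(ranked)
    m = int(hits.sum())
    if m == 0 or m == n:
        raise ValueError(f"signature overlap m={m} of N={n} leaves no contrast")
    w = np.abs(ranked.metric) ** weight
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum()
    if total <= 0:  # all overlap metrics are zero: fall back to uniform steps
        hit_w = hits / m
        total = 1.0
    deviation = np.cumsum(hit_w) / total - np.cumsum(~hits) / (n - m)
    peak = int(np.argmax(np.abs(deviation)))
    return float(deviation[peak]), peak


def leading_edge(
    ranked: RankedList, signature: frozenset[str], es: float, peak_index: int
) -> frozenset[str]:
    """Signature genes driving the enrichment: those at or before the peak
    for positive ES, at or after it for negative ES."""
    if es == 0:
        raise ValueError("leading edge undefined for es == 0")
    if es > 0:
        span = ranked.genes[: peak_index + 1]
    else:
        span = ranked.genes[peak_index:]
    return frozenset(g for g in span if g in signature)


def _permutation_es(
    abs_r_pow: np.ndarray, m: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` random size-``m`` gene sets, vectorized.

    Works from sorted hit positions: the running sum's extrema occur at a
    hit or immediately before one, so only 2m candidate deviations per
    permutation need evaluating.
    """
    n = abs_r_pow.shape[0]
    # sample m positions without replacement per permutation
    keys = rng.random((n_perm, n))
    idx = np.sort(np.argpartition(keys, m - 1, axis=1)[:, :m], axis=1)
    w = abs_r_pow[idx]
    totals = w.sum(axis=1, keepdims=True)
    w = np.where(totals > 0, w, 1.0 / m)
    totals = np.where(totals > 0, totals, 1.0)
    hit_cum = np.cumsum(w, axis=1) / totals
    j = np.arange(1, m + 1)
    miss_den = n - m
    dev_after = hit_cum - (idx + 1 - j) / miss_den
    prev = np.concatenate([np.zeros((n_perm, 1)), hit_cum[:, :-1]], axis=1)
    dev_before = prev - (idx - (j - 1)) / miss_den
    candidates = np.concatenate([dev_after, dev_before], axis=1)
    pick = np.argmax(np.abs(candidates), axis=1)
    return candidates[np.arange(n_perm), pick]


def _phenotype_permutation_es(
    dataset: ExpressionDataset,
    signature: frozenset[str],
    n_perm: int,
    rng: np.random.Generator,
    metric: str,
    weight: float,
) -> np.ndarray:
    values = dataset.values
    n_ctrl = len(dataset.control_ids)
    out = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(dataset.n_samples)
        shuffled = ExpressionDataset(
            name=dataset.name,
            genes=list(dataset.genes),
            samples=list(dataset.samples),
            values=values[:, perm],
            control_ids=dataset.samples[:n_ctrl],
            test_ids=dataset.samples[n_ctrl:],
        )
        ranked_b = rank_genes(shuffled, metric=metric)
        out[b], _ = enrichment_score(ranked_b, signature, weight=weight)
    return out


def normalize_and_test(
    es_observed: float,
    ranked: RankedList,
    signature: frozenset[str],
    n_perm: int = 1000,
    scheme: str = "gene_permutation",
    seed: int | None = 0,
    weight: float = 1.0,
    dataset: ExpressionDataset | None = None,
    metric: str = "signal_to_noise",
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation null for one signature: NES and nominal p-value.

    NES = es / mean(permuted ES of the same sign); p = add-one tail fraction
    among same-sign permuted values, so p is never exactly 0 and lies in
    [1/(k+1), 1].  Returns (nan, nan) when no permuted value shares the
    observed sign (NES undefined; callers flag and exclude the signature).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be at least 10")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = len(signature.intersection(ranked.genes))
    if scheme == "gene_permutation":
        abs_r_pow = np.abs(ranked.metric) ** weight
        perm = _permutation_es(abs_r_pow, m, n_perm, rng)
    elif scheme == "phenotype":
        if dataset is None:
            raise ValueError("phenotype permutation needs the dataset")
        perm = _phenotype_permutation_es(dataset, signature, n_perm, rng, metric, weight)
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if es_observed == 0:
        return 0.0, 1.0
    same_sign = perm > 0 if es_observed > 0 else perm < 0
    k = int(same_sign.sum())
    if k == 0:
        return float("nan"), float("nan")
    extreme = int((np.abs(perm[same_sign]) >= abs(es_observed)).sum())
    p_nominal = (1 + extreme) / (1 + k)
    nes = es_observed / abs(perm[same_sign].mean())
    return float(nes), float(p_nominal)


def page_zscore(ratios: pd.Series, signature: frozenset[str]) -> tuple[float, float]:
    """PAGE z-score of a signature over per-gene log2 ratios.

    z = (Sm - mu) * sqrt(m) / delta with mu, delta the mean and (sample)
    standard deviation of all gene-level values; p is the two-sided normal
    tail.
    """
    overlap = ratios.index.intersection(sorted(signature))
    m = len(overlap)
    if m < 1:
        raise ValueError("signature has no overlap with the ratio vector")
    mu = float(ratios.mean())
    delta = float(ratios.std(ddof=1))
    if not delta > 0:
        raise ValueError("degenerate contrast: zero spread of log2 ratios")
    z = (float(ratios.loc[overlap].mean()) - mu) * np.sqrt(m) / delta
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def gage_score(dataset: ExpressionDataset, signature: frozenset[str]) -> tuple[float, float]:
    """Simplified GAGE: per (test, control) pair, a two-sample t of the
    signature genes' log2 fold changes vs all genes; pairwise evidence
    combined into one signed Stouffer z and a two-sided p."""
    gene_in_sig = np.array([g in signature for g in dataset.genes])
    m = int(gene_in_sig.sum())
    if m < 2:
        raise ValueError(f"signature overlap m={m} too small for GAGE")
    ctrl, test = dataset.control_values, dataset.test_values
    zs = []
    for it in range(test.shape[1]):
        for ic in range(ctrl.shape[1]):
            lfc = test[:, it] - ctrl[:, ic]
            t_stat, p = stats.ttest_ind(lfc[gene_in_sig], lfc, equal_var=False)
            # signed z so that up- and down-enrichment aggregate coherently
            z = np.sign(t_stat) * stats.norm.isf(min(p / 2.0, 1.0 - 1e-16))
            zs.append(z)
    combined = float(np.sum(zs) / np.sqrt(len(zs)))
    p_combined = float(2.0 * stats.norm.sf(abs(combined)))
    return combined, p_combined


def profile_dataset(
    dataset: ExpressionDataset,
    collection: SignatureCollection,
    method: str = "gsea",
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    metric: str = "signal_to_noise",
    scheme: str = "gene_permutation",
) -> pd.DataFrame:
    """Score every signature of a (size-filtered) collection against one
    dataset.

    Returns a DataFrame indexed by signature with columns ``m``, ``es``
    (method statistic), ``nes`` (normalized score; equals the statistic for
    PAGE/GAGE), ``p_nominal``, ``fdr`` (BH across signatures) and
    ``leading_edge`` (frozenset; GSEA only, empty otherwise), plus a
    ``flag`` column naming any per-signature skip reason.  Skipped or
    NES-undefined signatures carry NaN statistics and are excluded from the
    BH adjustment; the profile itself never aborts.
    """
    if method not in {"gsea", "page", "gage"}:
        raise ValueError(f"unknown method {method!r}")
    names = list(collection.signatures)
    rows = []
    if method == "gsea":
        ranked = rank_genes(dataset, metric=metric)
        universe = set(ranked.genes)
        for i, name in enumerate(names):
            sig = collection[name] & universe
            m = len(sig)
            if m == 0 or m == len(ranked):
                rows.append((name, m, np.nan, np.nan, np.nan, frozenset(), "degenerate overlap"))
                continue
            es, peak = enrichment_score(ranked, sig, weight=weight)
            rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
            nes, p = normalize_and_test(
                es, ranked, sig, n_perm=n_perm, scheme=scheme, weight=weight,
                dataset=dataset, metric=metric, rng=rng,
            )
            if np.isnan(nes):
                rows.append((name, m, es, np.nan, np.nan, frozenset(), "nes undefined"))
                continue
            le = leading_edge(ranked, sig, es, peak) if es != 0 else frozenset()
            rows.append((name, m, es, nes, p, le, ""))
    else:
        ratios = log2_ratios(dataset)
        universe = set(dataset.genes)
        for name in names:
            sig = collection[name] & universe
            m = len(sig)
            try:
                if method == "page":
                    stat, p = page_zscore(ratios, sig)
                else:
                    stat, p = gage_score(dataset, sig)
            except ValueError as exc:
                rows.append((name, m, np.nan, np.nan, np.nan, frozenset(), str(exc)))
                continue
            rows.append((name, m, stat, stat, p, frozenset(), ""))
    frame = pd.DataFrame(
        rows,
        columns=["signature", "m", "es", "nes", "p_nominal", "leading_edge", "flag"],
    ).set_index("signature")
    frame["fdr"] = np.nan
    defined = frame["p_nominal"].notna()
    if defined.any():
        frame.loc[defined, "fdr"] = stats.false_discovery_control(
            frame.loc[defined, "p_nominal"].to_numpy(), method="bh"
        )
    return frame[["m", "es", "nes", "p_nominal", "fdr", "leading_edge", "flag"]]
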