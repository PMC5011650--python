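"""Running-sum enrichment score vs a brute-force oracle, permutation
normalization, PAGE and GAGE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stemsig.scoring as scoring
from stemsig import (SimulationConfig, enrichment_score, gage_score,
                     generate_collection, leading_edge, normalize_and_test,
                     page_zscore, profile_dataset, rank_genes)
from stemsig.io import SignatureCollection
from stemsig.scoring import RankedList

from conftest import make_dataset


def brute_force_es(genes, metric, signature, weight=1.0):
    """Independent loop: explicit hit/miss running sums, checks unit masses."""
    n = len(genes)
    hits = [g in signature for g in genes]
    m = sum(hits)
    denom = sum(abs(metric[i]) ** weight for i in range(n) if hits[i])
    p_hit = p_miss = 0.0
    best, peak = 0.0, 0
    for i in range(n):
        if hits[i]:
            p_hit += (abs(metric[i]) ** weight / denom) if denom > 0 else 1.0 / m
        else:
            p_miss += 1.0 / (n - m)
        if abs(p_hit - p_miss) > abs(best):
            best, peak = p_hit - p_miss, i
    assert p_hit == pytest.approx(1.0) and p_miss == pytest.approx(1.0)
    return best, peak


def random_fixture(rng, n_max=50):
    n = int(rng.integers(4, n_max + 1))
    genes = [f"g{i:03d}" for i in range(n)]
    metric = np.sort(rng.normal(0, 1, n))[::-1]
    m = int(rng.integers(1, n))
    signature = frozenset(rng.choice(genes, size=m, replace=False).tolist())
    return RankedList(genes=genes, metric=metric), signature


class TestRankGenes:
    def test_descending_order(self):
        values = np.array([[0, 0, 2, 2], [0, 0, 1, 1]], dtype=float)
        ranked = rank_genes(make_dataset(values + np.random.default_rng(0).normal(0, 0.01, values.shape), 2))
        assert ranked.genes == ["g0", "g1"]

    def test_ties_broken_lexicographically(self):
        ranked = RankedList(genes=["b", "a"], metric=np.array([1.0, 1.0]))
        values = np.ones((2, 4))
        ds = make_dataset(values, 2, genes=["b", "a"])
        assert rank_genes(ds).genes == ["a", "b"]

    def test_signal_to_noise_formula_with_floor(self):
        ctrl = np.array([[1.0, 2.0, 3.0]])
        test = np.array([[4.0, 5.0, 6.0]])
        ds = make_dataset(np.hstack([ctrl, test]), 3)
        expected_sd = lambda v: max(np.std(v, ddof=1), max(0.2 * abs(np.mean(v)), 0.2))
        expected = (5.0 - 2.0) / (expected_sd(test[0]) + expected_sd(ctrl[0]))
        assert scoring.signal_to_noise(ds)[0] == pytest.approx(expected)


class TestEnrichmentScore:
    def test_top_loaded_signature_reaches_one(self):
        ranked = RankedList(genes=list("abcdef"), metric=np.array([3, 2.5, 2, 1, 0.5, 0.1]))
        es, _ = enrichment_score(ranked, frozenset("ab"))
        assert es == pytest.approx(1.0)

    def test_worked_four_gene_example(self):
        ranked = RankedList(genes=list("abcd"), metric=np.array([4.0, 3.0, 2.0, 1.0]))
        es, peak = enrichment_score(ranked, frozenset("ac"))
        assert es == pytest.approx(2 / 3)
        assert peak == 0  # the top-ranked gene attains the maximum

    def test_bottom_loaded_signature_negative(self):
        ranked = RankedList(genes=list("abcdef"), metric=np.array([3, 2.5, 2, 1, 0.5, 0.1]))
        es, _ = enrichment_score(ranked, frozenset("ef"))
        assert es < 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            ranked, signature = random_fixture(rng)
            es, peak = enrichment_score(ranked, signature)
            es_bf, peak_bf = brute_force_es(ranked.genes, ranked.metric, signature)
            assert es == pytest.approx(es_bf, abs=1e-12)
            assert peak == peak_bf
            assert -1.0 <= es <= 1.0

    def test_degenerate_overlap_rejected(self):
        ranked = RankedList(genes=list("abcd"), metric=np.arange(4.0)[::-1])
        with pytest.raises(ValueError):
            enrichment_score(ranked, frozenset("xyz"))
        with pytest.raises(ValueError):
            enrichment_score(ranked, frozenset("abcd"))


class TestLeadingEdge:
    def test_positive_es_takes_genes_up_to_peak(self):
        ranked = RankedList(genes=list("abcd"), metric=np.array([4.0, 3.0, 2.0, 1.0]))
        es, peak = enrichment_score(ranked, frozenset("ac"))
        assert leading_edge(ranked, frozenset("ac"), es, peak) == {"a"}

    def test_top_loaded_leading_edge_is_whole_overlap(self):
        ranked = RankedList(genes=list("abcdef"), metric=np.array([3, 2.5, 2, 1, 0.5, 0.1]))
        sig = frozenset("ab")
        es, peak = enrichment_score(ranked, sig)
        assert leading_edge(ranked, sig, es, peak) == sig

    def test_negative_es_takes_tail(self):
        ranked = RankedList(genes=list("abcdef"), metric=np.array([3, 2.5, 2, 1, 0.5, 0.1]))
        sig = frozenset("ef")
        es, peak = enrichment_score(ranked, sig)
        edge = leading_edge(ranked, sig, es, peak)
        assert edge == sig and es < 0


class TestNormalizeAndTest:
    def _ranked(self):
        rng = np.random.default_rng(0)
        return RankedList(genes=[f"g{i}" for i in range(30)],
                          metric=np.sort(rng.normal(0, 1, 30))[::-1])

    def test_constant_null_gives_unit_nes_and_p_one(self, monkeypatch):
        ranked = self._ranked()
        monkeypatch.setattr(scoring, "_permutation_es", lambda *a, **k: np.full(100, 0.4))
        nes, p = normalize_and_test(0.4, ranked, frozenset(["g0", "g1"]), n_perm=100)
        assert nes == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_add_one_rule_when_observed_exceeds_null(self, monkeypatch):
        ranked = self._ranked()
        null = np.concatenate([np.full(40, 0.1), np.full(60, -0.1)])
        monkeypatch.setattr(scoring, "_permutation_es", lambda *a, **k: null)
        _, p = normalize_and_test(0.9, ranked, frozenset(["g0"]), n_perm=100)
        assert p == pytest.approx(1 / 41)

    def test_no_same_sign_null_flagged_undefined(self, monkeypatch):
        ranked = self._ranked()
        monkeypatch.setattr(scoring, "_permutation_es", lambda *a, **k: np.full(50, -0.2))
        nes, p = normalize_and_test(0.5, ranked, frozenset(["g0"]), n_perm=50)
        assert np.isnan(nes) and np.isnan(p)

    def test_deterministic_given_seed(self):
        ranked = self._ranked()
        sig = frozenset(["g0", "g3", "g9"])
        es, _ = enrichment_score(ranked, sig)
        a = normalize_and_test(es, ranked, sig, n_perm=200, seed=5)
        b = normalize_and_test(es, ranked, sig, n_perm=200, seed=5)
        assert a == b


class TestPage:
    def test_signature_mean_equal_to_background(self):
        ratios = pd.Series([1.0, -1.0, 2.0, -2.0], index=list("abcd"))
        z, p = page_zscore(ratios, frozenset(["a", "b"]))
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_worked_example(self):
        ratios = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        z, p = page_zscore(ratios, frozenset(["c", "d"]))
        assert z == pytest.approx(np.sqrt(2) / np.sqrt(5 / 3))
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)))

    def test_degenerate_spread_is_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            page_zscore(pd.Series([1.0, 1.0, 1.0], index=list("abc")), frozenset(["a"]))


class TestGage:
    def _dataset(self, seed=0, delta=0.0):
        rng = np.random.default_rng(seed)
        values = rng.normal(5, 0.5, size=(100, 6))
        values[:20, 3:] += delta
        return make_dataset(values, 3)

    def test_single_pair_equals_that_pairs_p(self):
        ds = self._dataset()
        single = make_dataset(ds.values[:, [0, 3]], 1)
        sig = frozenset([f"g{i}" for i in range(20)])
        _, p_combined = gage_score(single, sig)
        lfc = single.values[:, 1] - single.values[:, 0]
        in_sig = np.array([g in sig for g in single.genes])
        _, p_pair = stats.ttest_ind(lfc[in_sig], lfc, equal_var=False)
        assert p_combined == pytest.approx(p_pair, rel=1e-9)

    def test_no_signal_combined_p_near_one(self):
        ds = self._dataset(seed=1, delta=0.0)
        ps = [gage_score(ds, frozenset(np.random.default_rng(s).choice(
            ds.genes, 15, replace=False).tolist()))[1] for s in range(10)]
        assert np.median(ps) > 0.2

    def test_planted_module_detected(self):
        ps = [gage_score(self._dataset(seed=s, delta=2.0),
                         frozenset([f"g{i}" for i in range(20)]))[1] for s in range(5)]
        assert np.median(ps) < 1e-3

    def test_tiny_overlap_rejected(self):
        with pytest.raises(ValueError, match="m="):
            gage_score(self._dataset(), frozenset(["g0"]))


class TestProfileDataset:
    def test_empty_collection_gives_empty_profile(self):
        ds = self._planted()
        profile = profile_dataset(ds, SignatureCollection({}, ""), n_perm=50)
        assert profile.empty

    def _planted(self):
        config = SimulationConfig(
            n_genes=400, genotypes=(("A", 1, {"mod": 3.0}),), noise_sd=0.25,
            modules={"mod": 30}, n_decoy_signatures=15, n_related_per_module=0,
            n_control=4, n_test=4, seed=6,
        )
        return generate_collection(config)[0][0]

    def test_planted_module_ranks_first_by_abs_nes(self):
        config = SimulationConfig(
            n_genes=400, genotypes=(("A", 1, {"mod": 3.0}),), noise_sd=0.25,
            modules={"mod": 30}, n_decoy_signatures=15, n_related_per_module=0,
            n_control=4, n_test=4, seed=6,
        )
        datasets, collection, _ = generate_collection(config)
        profile = profile_dataset(datasets[0], collection, n_perm=200, seed=1)
        assert profile["nes"].abs().idxmax() == "MODULE_MOD"

    def test_identical_seed_identical_profile(self):
        config = SimulationConfig(
            n_genes=300, genotypes=(("A", 1, {"mod": 2.0}),),
            modules={"mod": 20}, n_decoy_signatures=10, n_related_per_module=0,
            n_control=3, n_test=3, seed=2,
        )
        datasets, collection, _ = generate_collection(config)
        a = profile_dataset(datasets[0], collection, n_perm=100, seed=9)
        b = profile_dataset(datasets[0], collection, n_perm=100, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_fdr_is_bh_over_nominal_p(self):
        config = SimulationConfig(
            n_genes=300, genotypes=(("A", 1, {"mod": 2.0}),),
            modules={"mod": 20}, n_decoy_signatures=10, n_related_per_module=0,
            n_control=3, n_test=3, seed=2,
        )
        datasets, collection, _ = generate_collection(config)
        profile = profile_dataset(datasets[0], collection, n_perm=100, seed=9)
        expected = stats.false_discovery_control(profile["p_nominal"].to_numpy(), method="bh")
        np.testing.assert_allclose(profile["fdr"], expected)
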