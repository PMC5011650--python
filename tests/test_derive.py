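"""CGS and URG/DRG derivation: frequency tallies, the top-5% rule and NES
sign consistency."""

import numpy as np
import pandas as pd
import pytest

from stemsig import (extract_cgs, rank_and_threshold_signatures,
                     select_urg_drg)
from stemsig.derive import SignatureConsistencySets, _top_frequency_genes


def profile_frame(records):
    """Build a per-dataset profile frame from {signature: (nes, p, edge)}."""
    rows = [
        {"signature": s, "m": len(edge), "es": nes / 3, "nes": nes,
         "p_nominal": p, "fdr": p, "leading_edge": frozenset(edge), "flag": ""}
        for s, (nes, p, edge) in records.items()
    ]
    return pd.DataFrame(rows).set_index("signature")


class TestExtractCgs:
    def test_single_signature_single_dataset(self):
        profiles = {"d1": profile_frame({"S": (2.0, 0.01, {"a", "b"})})}
        cgs = extract_cgs(["S"], profiles)
        assert cgs.genes == {"a", "b"}
        assert cgs.frequency == {"a": 1, "b": 1}

    def test_ubiquitous_gene_always_selected(self):
        profiles = {"d1": profile_frame({
            f"S{i}": (2.0, 0.01, {"hub", f"x{i}"}) for i in range(20)
        })}
        cgs = extract_cgs([f"S{i}" for i in range(20)], profiles)
        assert "hub" in cgs.genes
        assert cgs.frequency["hub"] == 20

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(60)]
        sigs = {}
        for i in range(30):
            edge = set(rng.choice(genes, size=rng.integers(3, 15), replace=False).tolist())
            sigs[f"S{i:02d}"] = (1.0, 0.01, edge)
        profiles = {"d1": profile_frame(sigs)}
        cgs = extract_cgs(list(sigs), profiles, top_frac=0.1)
        # brute-force frequency count
        freq = {}
        for _, (_, _, edge) in sigs.items():
            for g in edge:
                freq[g] = freq.get(g, 0) + 1
        assert all(cgs.frequency[g] == freq[g] for g in cgs.genes)
        n_take = int(np.ceil(0.1 * len(freq)))
        cutoff = sorted(freq.values(), reverse=True)[n_take - 1]
        assert cgs.genes == {g for g, f in freq.items() if f >= cutoff}

    def test_union_across_datasets_counts_signatures_once(self):
        profiles = {
            "d1": profile_frame({"S": (2.0, 0.01, {"a"})}),
            "d2": profile_frame({"S": (2.0, 0.01, {"a", "b"})}),
        }
        cgs = extract_cgs(["S"], profiles)
        assert cgs.frequency["a"] == 1  # one signature, not two incidences

    def test_empty_cluster_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            extract_cgs([], {})


class TestTopFivePercentRule:
    def test_6002_distinct_sums_retain_exactly_300(self):
        rng = np.random.default_rng(0)
        n = 6002
        names = [f"S{i:05d}" for i in range(n)]
        p = rng.uniform(1e-8, 1.0, n)
        nes = rng.normal(0, 1, n)
        frame = pd.DataFrame({"nes": nes, "p_nominal": p,
                              "leading_edge": [frozenset()] * n, "flag": ""},
                             index=pd.Index(names, name="signature"))
        cons = rank_and_threshold_signatures({"d1": frame})
        assert len(cons.top_signatures) == 300

    def test_mixed_nes_signs_in_neither_set(self):
        frames = {
            "d1": profile_frame({f"S{i}": (+1.0 if i != 0 else +1.0, 1e-6, {"a"})
                                 for i in range(20)}),
            "d2": profile_frame({f"S{i}": (-1.0 if i == 0 else +1.0, 1e-6, {"a"})
                                 for i in range(20)}),
        }
        cons = rank_and_threshold_signatures(frames, top_frac=0.5)
        assert "S0" not in cons.pns and "S0" not in cons.nns
        assert set(cons.pns) == {f"S{i}" for i in range(1, 20)} & set(cons.top_signatures)

    def test_single_dataset_degenerate_consistency(self):
        frame = profile_frame({
            "UP": (2.0, 1e-8, {"a"}), "DOWN": (-2.0, 1e-7, {"b"}),
            "WEAK1": (0.5, 0.9, {"c"}), "WEAK2": (0.1, 0.95, {"d"}),
        })
        cons = rank_and_threshold_signatures({"d1": frame}, top_frac=0.5)
        assert cons.pns == ["UP"] and cons.nns == ["DOWN"]

    def test_sum_ranking_equals_product_of_p_ranking(self):
        rng = np.random.default_rng(3)
        frames = {
            d: profile_frame({f"S{i}": (1.0, rng.uniform(1e-6, 1), {"a"})
                              for i in range(40)})
            for d in ("d1", "d2", "d3")
        }
        by_sum = rank_and_threshold_signatures(frames, top_frac=0.25, aggregate="sum")
        # ranking by sum of -log p is ranking by product of p-values
        prod_p = np.ones(40)
        for frame in frames.values():
            prod_p *= frame["p_nominal"].to_numpy()
        expected = [f"S{i}" for i in np.argsort(prod_p)[:10]]
        assert set(by_sum.top_signatures) == set(expected)


class TestUrgDrg:
    def test_empty_pns_gives_empty_urg(self, caplog):
        cons = SignatureConsistencySets(pns=[], nns=["S"], summed_neglogp=pd.Series(dtype=float),
                                        top_signatures=["S"])
        profiles = {"d1": profile_frame({"S": (-2.0, 0.01, {"a", "b"})})}
        with caplog.at_level("WARNING"):
            urg, drg = select_urg_drg(cons, profiles)
        assert urg.genes == frozenset()
        assert drg.genes == {"a", "b"}

    def test_frequency_equals_brute_force_incidence_count(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(40)]
        sigs = {f"S{i}": (2.0, 0.001,
                          set(rng.choice(genes, size=10, replace=False).tolist()))
                for i in range(12)}
        profiles = {"d1": profile_frame(sigs)}
        cons = SignatureConsistencySets(pns=list(sigs), nns=[],
                                        summed_neglogp=pd.Series(dtype=float),
                                        top_signatures=list(sigs))
        urg, _ = select_urg_drg(cons, profiles, top_frac=0.2)
        freq = {}
        for _, (_, _, edge) in sigs.items():
            for g in edge:
                freq[g] = freq.get(g, 0) + 1
        assert all(urg.frequency[g] == freq[g] for g in urg.genes)

    def test_ties_at_cutoff_included(self):
        freq = {"a": 5, "b": 5, "c": 5, "d": 1}
        assert _top_frequency_genes(freq, top_frac=0.25) == {"a", "b", "c"}
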