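"""Subsample enumeration, consensus calls, ranking, orthologs, merging."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from depsig.signature import (ConsensusSignature, consensus_signature,
                              enumerate_rounds, map_orthologs, merge_panels,
                              rank_top_k)
from depsig.synth import RatSimConfig, gen_rat_experiment

from conftest import make_expr


class TestEnumerateRounds:
    @pytest.mark.parametrize("n_t,n_c,k,expected",
                             [(5, 5, 4, 25), (4, 4, 4, 1), (6, 6, 5, 36)])
    def test_round_counts(self, n_t, n_c, k, expected):
        assert len(enumerate_rounds(n_t, n_c, k)) == expected

    def test_rounds_are_distinct_and_ordered(self):
        rounds = enumerate_rounds(5, 5, 4)
        assert len(set(rounds)) == 25
        assert rounds == sorted(rounds)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 7), st.integers(1, 7), st.integers(1, 7))
    def test_count_equals_binomial_product(self, n_t, n_c, k):
        if k > min(n_t, n_c):
            with pytest.raises(ValueError):
                enumerate_rounds(n_t, n_c, k)
        else:
            assert len(enumerate_rounds(n_t, n_c, k)) == (
                math.comb(n_t, k) * math.comb(n_c, k)
            )

    def test_k_zero_rejected(self):
        with pytest.raises(ValueError):
            enumerate_rounds(5, 5, 0)


class TestConsensus:
    def test_planted_gene_has_full_support(self):
        # strong planted signal: every leave-one-out round calls it down
        rng = np.random.default_rng(0)
        vals = rng.normal(7, 0.2, size=(50, 10))
        vals[0, :5] -= 1.5
        M = make_expr(vals, ["t"] * 5 + ["c"] * 5)
        cols = list(M.samples)
        sig = consensus_signature(M, cols[:5], cols[5:])
        assert "g1" in sig.index
        assert sig.loc["g1", "support"] == 1.0
        assert sig.loc["g1", "direction"] == -1

    def test_null_genes_have_low_support(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            M = make_expr(rng.normal(7, 0.3, size=(200, 10)),
                          ["t"] * 5 + ["c"] * 5)
            cols = list(M.samples)
            est = ConsensusSignature().fit(M, cols[:5], cols[5:])
            assert est.support_["support"].max() <= 0.2

    def test_strict_rule_excludes_partial_support(self):
        # one treated animal of g2 is pushed so far that rounds
        # containing it see a near-zero fold change; only the 5 rounds
        # excluding it call g2, so full-support consensus drops it
        rng = np.random.default_rng(1)
        vals = rng.normal(7, 0.05, size=(30, 10))
        vals[0, :5] -= 3.0               # clean planted gene
        vals[1, :5] -= 3.0
        vals[1, 4] += 12.0               # corrupted treated animal
        M = make_expr(vals, ["t"] * 5 + ["c"] * 5)
        cols = list(M.samples)
        strict = ConsensusSignature(min_support=1.0).fit(M, cols[:5], cols[5:])
        assert "g1" in strict.signature_.index
        assert "g2" not in strict.signature_.index
        assert 0 < strict.support_.loc["g2", "support"] < 1
        lenient = ConsensusSignature(min_support=0.15).fit(
            M, cols[:5], cols[5:]
        )
        assert "g2" in lenient.signature_.index

    def test_signature_is_support_thresholded(self, rat_sim):
        M, _ = rat_sim
        est = ConsensusSignature().fit(
            M, M.group_samples("parous_dep"), M.group_samples("parous_vehicle")
        )
        expect = est.support_[est.support_["support"] >= 0.8]
        assert set(est.signature_.index) == set(expect.index)


class TestRankTopK:
    def test_ranks_by_absolute_median_difference(self):
        vals = np.array([
            [0, 0, 2, 2],    # diff -2
            [0, 0, 1, 1],    # diff -1
            [0.5, 0.5, 0, 0],  # diff +0.5
        ])
        M = make_expr(vals, ["t", "t", "c", "c"])
        top = rank_top_k(M, ["s1", "s2"], ["s3", "s4"], ["g1", "g2", "g3"], 2)
        assert list(top.index) == ["g1", "g2"]

    def test_k_larger_than_gene_list(self):
        M = make_expr([[1, 2], [3, 4]], ["t", "c"])
        top = rank_top_k(M, ["s1"], ["s2"], ["g1", "g2"], 10)
        assert len(top) == 2

    def test_tie_breaks_lexicographically(self):
        M = make_expr([[1, 0], [0, 1]], ["t", "c"])
        top = rank_top_k(M, ["s1"], ["s2"], ["g2", "g1"], 1)
        assert list(top.index) == ["g1"]

    def test_invalid_k(self):
        M = make_expr([[1, 2]], ["t", "c"])
        with pytest.raises(ValueError):
            rank_top_k(M, ["s1"], ["s2"], ["g1"], 0)


class TestOrthologMapping:
    def test_coverage_counts(self):
        genes = [f"r{i}" for i in range(100)]
        omap = pd.DataFrame({"rat_gene": genes[:91],
                             "human_gene": [f"H{i}" for i in range(91)]})
        mapped, unmapped, _ = map_orthologs(genes, omap)
        assert len(mapped) == 91
        assert len(unmapped) == 9

    def test_empty_map(self):
        omap = pd.DataFrame({"rat_gene": [], "human_gene": []})
        mapped, unmapped, _ = map_orthologs(["a", "b"], omap)
        assert mapped == [] and unmapped == ["a", "b"]

    def test_shared_symbol_deduplicated_with_sources(self):
        omap = pd.DataFrame({"rat_gene": ["r1", "r2"],
                             "human_gene": ["H", "H"]})
        mapped, unmapped, sources = map_orthologs(["r1", "r2"], omap)
        assert mapped == ["H"]
        assert sources["H"] == ["r1", "r2"]

    def test_one_to_two_map_rejected(self):
        omap = pd.DataFrame({"rat_gene": ["r1", "r1"],
                             "human_gene": ["H1", "H2"]})
        with pytest.raises(ValueError):
            map_orthologs(["r1"], omap)


def _panel(genes, direction=-1):
    return pd.DataFrame(
        {"direction": direction, "score": 1.0, "support": 1.0},
        index=pd.Index(genes, name="gene"),
    )


class TestMergePanels:
    def test_published_panel_arithmetic(self):
        parous = _panel([f"P{i}" for i in range(73)] + [f"S{i}" for i in range(18)])
        nulli = _panel([f"N{i}" for i in range(16)] + [f"S{i}" for i in range(18)])
        merged = merge_panels(parous, nulli)
        assert len(merged) == 107
        origins = merged.table["origin"].value_counts()
        assert origins["both"] == 18
        assert origins["parous"] == 73
        assert origins["nulliparous"] == 16

    def test_disjoint_and_identical(self):
        assert len(merge_panels(_panel(["a", "b", "c"]), _panel(["d", "e"]))) == 5
        same = merge_panels(_panel(["a", "b"]), _panel(["a", "b"]))
        assert (same.table["origin"] == "both").all()

    def test_direction_conflict_rejected(self):
        with pytest.raises(ValueError):
            merge_panels(_panel(["a"], -1), _panel(["a"], +1))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_cardinality_identity(self, a, b):
        pa = _panel([f"g{i}" for i in sorted(a)])
        pb = _panel([f"g{i}" for i in sorted(b)])
        assert len(merge_panels(pa, pb)) == len(a) + len(b) - len(a & b)


class TestEndToEndRecovery:
    def test_planted_signature_recovered(self, rat_sim):
        """Consensus + top-K on the seeded simulation recovers the
        planted down-regulated genes with few false calls."""
        M, planted = rat_sim
        treated = M.group_samples("parous_dep")
        control = M.group_samples("parous_vehicle")
        cons = consensus_signature(M, treated, control)
        ranked = rank_top_k(M, treated, control, list(cons.index), 100)
        got = set(ranked.index)
        assert len(got & set(planted)) >= 45
        assert len(got - set(planted)) <= 5
        assert (cons.loc[list(got), "direction"] == -1).all()
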