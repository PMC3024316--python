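"""Introgression-line statistics: expectations, tests, LD, network assembly."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fgunet.il_network import (ag_probability, ag_probability_test,
                               collapse_linked_loci, construct_network,
                               detect_fgus, expected_introgression, ld_prime,
                               single_locus_excess_test)


class TestIntrogressionExpectation:
    def test_bc3f2_frequencies(self):
        exp = expected_introgression(3, 1)
        assert exp.allele_frequency == Fraction(1, 16)
        assert exp.genotype_frequencies == (Fraction(29, 32), Fraction(1, 16),
                                            Fraction(1, 32))
        assert exp.carrier_frequency == Fraction(3, 32)

    def test_bc1f2_allele_frequency(self):
        assert expected_introgression(1, 1).allele_frequency == Fraction(1, 4)

    def test_genotype_frequencies_sum_to_one(self):
        for k in range(5):
            for m in range(4):
                exp = expected_introgression(k, m)
                assert sum(exp.genotype_frequencies) == 1
                g = exp.genotype_frequencies
                assert exp.allele_frequency == g[1] / 2 + g[2]

    def test_invalid_scheme(self):
        with pytest.raises(ValueError):
            expected_introgression(-1, 1)


def _matrix(columns: dict[str, list[int]]) -> pd.DataFrame:
    n = len(next(iter(columns.values())))
    return pd.DataFrame(columns, index=[f"L{i}" for i in range(n)], dtype=float)


class TestSingleLocusTest:
    def test_matching_expectation_gives_chi2_zero(self):
        exp = expected_introgression(3, 1)
        col = [0] * 29 + [1] * 2 + [2] * 1
        m = _matrix({"x": col})
        stat, p = single_locus_excess_test(m, "x", exp, "genotypic")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_strong_excess_is_significant(self):
        """53 of 71 carriers against a neutral 3/32 expectation."""
        exp = expected_introgression(3, 1)
        col = [2] * 30 + [1] * 23 + [0] * 18
        m = _matrix({"x": col})
        for kind in ("carrier", "allelic", "genotypic"):
            _, p = single_locus_excess_test(m, "x", exp, kind)
            assert p < 1e-4

    def test_all_missing_locus_raises(self):
        exp = expected_introgression(3, 1)
        m = _matrix({"x": [0] * 10})
        m["x"] = np.nan
        with pytest.raises(ValueError):
            single_locus_excess_test(m, "x", exp)


class TestAGProbability:
    def test_binomial_extreme_case(self):
        assert ag_probability(0.5, 4, 4) == pytest.approx(0.0625)

    def test_direct_arithmetic(self):
        assert ag_probability(0.1, 3, 2) == pytest.approx(0.009)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.01, 0.99), st.integers(1, 60))
    def test_lower_bounds_exact_binomial_tail(self, p_i, n):
        """For full co-introgression (m = n) the AG probability equals the
        binomial point mass; generally it lower-bounds the exact tail."""
        m = n  # perfect association case
        assert ag_probability(p_i, n, m) == pytest.approx(
            float(stats.binom.pmf(m, n, p_i)))
        m2 = n // 2
        assert ag_probability(p_i, n, m2) <= float(stats.binom.sf(m2 - 1, n, p_i)) + 1e-12

    def test_pairwise_count(self):
        exp = expected_introgression(3, 1)
        cols = {f"x{i}": [1] * 4 + [0] * 8 for i in range(3)}
        res = ag_probability_test(_matrix(cols), list(cols), exp)
        assert len(res["pair_p"]) == 3  # r(r-1)/2 with r = 3
        assert res["perfect"]

    def test_mismatch_allowance(self):
        exp = expected_introgression(3, 1)
        m = _matrix({"a": [1, 1, 1, 0, 0, 0], "b": [1, 1, 0, 0, 0, 0]})
        strict = ag_probability_test(m, ["a", "b"], exp, max_mismatch=0)
        loose = ag_probability_test(m, ["a", "b"], exp, max_mismatch=1)
        assert not strict["association_ok"]
        assert loose["association_ok"]


class TestLDPrime:
    def test_identical_carrier_sets(self):
        m = _matrix({"a": [2, 1, 0, 0, 0, 0], "b": [1, 2, 0, 0, 0, 0]})
        d, dp = ld_prime(m, "a", "b")
        assert dp == pytest.approx(1.0)

    def test_mutually_exclusive_carriers(self):
        m = _matrix({"a": [1, 1, 1, 0, 0, 0], "b": [0, 0, 0, 1, 1, 1]})
        d, dp = ld_prime(m, "a", "b")
        assert dp == pytest.approx(-1.0)

    def test_independent_loci_near_zero(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame({"a": rng.choice([0, 1], 4000, p=[0.7, 0.3]),
                          "b": rng.choice([0, 1], 4000, p=[0.7, 0.3])},
                         dtype=float)
        d, _ = ld_prime(m, "a", "b")
        assert abs(d) < 0.02

    def test_monomorphic_raises(self):
        m = _matrix({"a": [1, 1, 1], "b": [1, 0, 1]})
        with pytest.raises(ValueError):
            ld_prime(m, "a", "b")


class TestCollapseAndNetwork:
    def test_linked_duplicates_collapse(self):
        m = _matrix({"a": [1, 0, 1, 0], "a2": [1, 0, 1, 0], "c": [0, 1, 0, 1]})
        out = collapse_linked_loci(m, bins={"a": "bin1", "a2": "bin1", "c": "bin2"})
        assert list(out.columns) == ["a", "c"]

    def test_unlinked_correlates_both_retained(self):
        m = _matrix({"a": [1, 0, 1, 0], "b": [1, 0, 1, 0]})
        out = collapse_linked_loci(m, bins={"a": "bin1", "b": "bin7"})
        assert list(out.columns) == ["a", "b"]

    def test_map_free_pass_through(self):
        m = _matrix({"a": [1, 0], "b": [0, 1]})
        assert collapse_linked_loci(m, None) is m

    def test_single_call_single_node(self):
        from fgunet.il_network import FGUCall
        call = FGUCall("single-locus", ("x",), frozenset({"L1"}), 0.5, 1e-6)
        net = construct_network([call], _matrix({"x": [1, 0]}))
        assert net.number_of_nodes() == 1
        assert net.number_of_edges() == 0

    def test_disjoint_carriers_become_antagonism(self):
        from fgunet.il_network import FGUCall
        carriers_a = frozenset(f"L{i}" for i in range(0, 3))
        carriers_b = frozenset(f"L{i}" for i in range(3, 6))
        m = _matrix({"x": [1, 1, 1, 0, 0, 0], "y": [0, 0, 0, 1, 1, 1]})
        calls = [FGUCall("single-locus", ("x",), carriers_a, 0.5, 1e-6),
                 FGUCall("single-locus", ("y",), carriers_b, 0.5, 1e-6)]
        net = construct_network(calls, m)
        assert len(net.graph["groups"]) == 2
        assert any(d["relation"] == "antagonism" for *_, d in net.edges(data=True))

    def test_inclusion_creates_layering(self):
        from fgunet.il_network import FGUCall
        all_lines = frozenset(f"L{i}" for i in range(6))
        subset = frozenset(f"L{i}" for i in range(3))
        m = _matrix({"u": [1] * 6, "d": [1, 1, 1, 0, 0, 0]})
        calls = [FGUCall("single-locus", ("u",), all_lines, 1.0, 1e-9),
                 FGUCall("single-locus", ("d",), subset, 0.5, 1e-6)]
        net = construct_network(calls, m)
        assert net.has_edge("u", "d")
        assert net.edges["u", "d"]["relation"] == "regulates"

    def test_order_invariance(self):
        from fgunet.il_network import FGUCall
        m = _matrix({"x": [1, 1, 0, 0], "y": [1, 1, 0, 0], "z": [0, 0, 1, 1]})
        calls = [FGUCall("single-locus", (c,), frozenset(m.index[m[c] > 0]), 0.5, 1e-6)
                 for c in m.columns]
        net1 = construct_network(calls, m)
        net2 = construct_network(calls[::-1], m[["z", "y", "x"]])
        assert set(net1.nodes) == set(net2.nodes)
        assert set(net1.edges) == set(net2.edges)
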