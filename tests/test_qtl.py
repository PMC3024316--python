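"""Expected QTL parameters: counts, contrasts, closed forms, variance shares."""

from fractions import Fraction
from itertools import combinations

import pytest

from fgunet.model import materialize_scenario
from fgunet.population import (enumerate_population, population_moments,
                               scenario_population)
from fgunet.qtl import (classify_subset, closed_form_effect,
                        closed_form_main_effect, contrast_effect,
                        count_parameters, differentiated_allele_pathway_means,
                        expected_epistasis, expected_main_effect,
                        functional_genotype_frequency, pathway_effect_from_qtl,
                        predict_genotype_value, variance_decomposition)


class TestParameterCounts:
    @pytest.mark.parametrize("k, main, t1, t2", [
        (1, 2, 0, 0), (2, 4, 0, 0), (3, 6, 4, 0), (4, 7, 14, 0),
        (5, 6, 10, 5), (6, 7, 10, 5), (7, 8, 9, 4)])
    def test_fd_splits_for_all_scenarios(self, k, main, t1, t2):
        c = count_parameters(k)
        assert (c.n_main, c.n_type1, c.n_type2) == (main, t1, t2)

    def test_n1_column(self):
        assert [count_parameters(k).n1 for k in range(1, 8)] == \
            [2, 4, 10, 21, 21, 22, 21]

    def test_single_locus_counts(self, model2):
        from fgunet.model import Locus
        m = model2.copy()
        m.add_locus(Locus("x", "B11"))
        c = count_parameters(model=m, loci=["x"])
        assert (c.n_main, c.n_type1, c.n_type2, c.n1) == (1, 0, 0, 1)

    def test_subset_classification(self):
        m, loci = materialize_scenario(6)
        assert classify_subset(m, ["B11.1", "B11.2"]) == "II"
        assert classify_subset(m, ["T1.1", "B11.1"]) == "I"
        assert classify_subset(m, ["T1.1", "B11.1", "B11.2"]) == "I"
        assert classify_subset(m, ["B11.1", "B21.1"]) is None
        assert classify_subset(m, ["T1.1", "T2.1"]) is None


class TestMainEffects:
    def test_half_unit_effect_without_other_segregation(self):
        table = scenario_population(1, "RI", "D")
        assert expected_main_effect(table, "T1.1") == 8

    def test_fixed_null_sibling_discounts_subtree(self):
        # T2's subtree realizes 8 + 4 because B23 carries a shared mutant
        table = scenario_population(1, "RI", "D")
        assert expected_main_effect(table, "T2.1") == 6

    def test_f2_dominance_uses_homozygote_contrast(self):
        m, loci = materialize_scenario(4)
        table = scenario_population(4, "F2", "D")
        a = expected_main_effect(table, "B11.1")
        assert a == Fraction(1, 2) * 4 * Fraction(3, 4) ** 2  # = 1.125

    def test_not_segregating_raises(self):
        table = scenario_population(1, "RI", "D")
        with pytest.raises(Exception):
            expected_main_effect(table, "S.1")


class TestEpistasis:
    def test_ri_type1_equals_downstream_main(self):
        table = scenario_population(3, "RI", "D")
        l = expected_epistasis(table, ["T1.1", "B11.1"])
        assert l == 1 == expected_main_effect(table, "B11.1")

    def test_different_b_units_are_independent(self):
        table = scenario_population(2, "RI", "D")
        for pair in combinations(table.loci, 2):
            assert expected_epistasis(table, pair) == 0

    def test_f2_two_thirds_rule_and_cascade(self):
        m, loci = materialize_scenario(4)
        table = scenario_population(4, "F2", "D")
        a_b11 = expected_main_effect(table, "B11.1")
        l2 = expected_epistasis(table, ["T1.1", "B11.1"])
        l3 = expected_epistasis(table, ["S.1", "T1.1", "B11.1"])
        assert l2 == Fraction(2, 3) * a_b11
        assert l3 == Fraction(2, 3) * l2

    def test_ri_high_order_equality(self):
        table = scenario_population(6, "RI", "D")
        a = expected_main_effect(table, "B11.1")
        assert expected_epistasis(table, ["T1.1", "B11.1", "B11.2"]) == a


class TestClosedFormOracle:
    @pytest.mark.parametrize("k", range(1, 8))
    @pytest.mark.parametrize("pop", ["RI", "F2"])
    @pytest.mark.parametrize("mode", ["D", "A", "DA"])
    def test_closed_form_equals_enumeration_contrast(self, k, pop, mode):
        """The Theorem closed forms reproduce every enumeration contrast
        (orders 1-3) exactly, for every scenario, population and mode."""
        model, loci = materialize_scenario(k)
        table = scenario_population(k, pop, mode)
        for size in (1, 2, 3):
            for sub in combinations(loci, size):
                if size > 1 and classify_subset(model, sub) is None:
                    continue
                cf = closed_form_effect(model, loci, sub, pop, mode)
                ct = contrast_effect(table, sub)
                assert abs(cf - ct) < Fraction(1, 10 ** 9), (k, pop, mode, sub)

    def test_functional_genotype_frequencies(self):
        assert functional_genotype_frequency("B", "RI", "D") == Fraction(1, 2)
        assert functional_genotype_frequency("B", "F2", "D") == Fraction(3, 4)
        assert functional_genotype_frequency("B", "F2", "DA") == Fraction(1, 2)
        assert functional_genotype_frequency("T", "F2", "DA") == Fraction(3, 4)

    def test_scenario3_ri_closed_form_example(self):
        model, loci = materialize_scenario(3)
        assert closed_form_main_effect(model, loci, "B11.1", "RI", "D") == 1


class TestPathwayEffectInversion:
    def test_co_adapted_pair(self, co_adapted_model):
        table = enumerate_population(co_adapted_model, ["A", "B"], "RI", "D")
        assert expected_main_effect(table, "A") == 0
        assert expected_main_effect(table, "B") == 0
        l = expected_epistasis(table, ["A", "B"])
        assert l == 2
        assert pathway_effect_from_qtl(l, [], "RI", co_adapted=True) == 4

    def test_single_locus_unit_inversion(self):
        assert pathway_effect_from_qtl(8, [], "RI") == 16

    def test_downstream_inversion_with_upstream_context(self):
        # scenario 3 RI: A(B11) = 1 with one segregating T locus upstream
        assert pathway_effect_from_qtl(1, ["T"], "RI") == 4


class TestVarianceDecomposition:
    def test_scenario1_ri_shares(self):
        model, _ = materialize_scenario(1)
        table = scenario_population(1, "RI", "D")
        terms, residual = variance_decomposition(table, model)
        shares = {sub: float(s) for sub, (_, s) in terms.items()}
        assert shares[("T1.1",)] == pytest.approx(64 / 100)
        assert shares[("T2.1",)] == pytest.approx(36 / 100)
        assert residual == 0

    def test_ri_shares_sum_to_one(self):
        for k in (2, 3, 6):
            model, _ = materialize_scenario(k)
            table = scenario_population(k, "RI", "D")
            _, residual = variance_decomposition(table, model)
            assert residual == 0

    def test_co_adapted_variance_is_pure_epistasis(self, co_adapted_model):
        table = enumerate_population(co_adapted_model, ["A", "B"], "RI", "D")
        terms, residual = variance_decomposition(table, co_adapted_model)
        assert terms[("A",)][1] == 0 and terms[("B",)][1] == 0
        assert terms[("A", "B")][1] == 1
        assert residual == 0


class TestGenotypePrediction:
    def test_ri_conventions_coincide(self):
        table = scenario_population(3, "RI", "D")
        for gi in (0, 2):
            for gj in (0, 2):
                g = {"T1.1": gi, "B11.1": gj}
                assert predict_genotype_value(table, g, "model2") == \
                    predict_genotype_value(table, g, "classical")

    def test_f2_classical_overestimates(self):
        table = scenario_population(3, "F2", "D")
        for gi in (0, 2):
            for gj in (0, 2):
                g = {"T1.1": gi, "B11.1": gj}
                classical = predict_genotype_value(table, g, "classical")
                model2 = predict_genotype_value(table, g, "model2")
                assert classical >= model2

    def test_mean_epistatic_deviation_identical(self):
        """The epistatic deviation of the four digenic classes averages to
        the same value under the pathway and classical conventions (RI:
        equal class frequencies make the corner mean the population mean)."""
        table = scenario_population(3, "RI", "D")
        mean, _ = population_moments(table)
        a_i = expected_main_effect(table, "T1.1")
        a_j = expected_main_effect(table, "B11.1")
        l = expected_epistasis(table, ["T1.1", "B11.1"])
        dev_m2 = dev_cl = Fraction(0)
        for gi in (0, 2):
            for gj in (0, 2):
                g = {"T1.1": gi, "B11.1": gj}
                zi, zj = gi - 1, gj - 1
                additive = mean + a_i * zi + a_j * zj
                dev_m2 += predict_genotype_value(table, g, "model2") - additive
                dev_cl += l * zi * zj
        assert dev_m2 / 4 == dev_cl / 4 == 0


class TestDifferentiatedAlleles:
    def test_co_adapted_group_means(self, co_adapted_model):
        groups = differentiated_allele_pathway_means(
            co_adapted_model, "Bc", ["A", "B"], "RI")
        assert groups[(2, 2)] == 4 and groups[(0, 0)] == 4
        assert groups[(2, 0)] == 0 and groups[(0, 2)] == 0

    def test_equal_weights_reduce_to_fixed_functional(self):
        from fgunet.model import FunctionalGeneticUnit, Locus, PathwayModel
        units = [FunctionalGeneticUnit("S", "S"),
                 FunctionalGeneticUnit("T1", "T", parent="S"),
                 FunctionalGeneticUnit("Bv", "B", parent="T1", effect=6.0)]
        m = PathwayModel(units)
        m.add_locus(Locus("v", "Bv", weights=(1.0, 1.0)))
        groups = differentiated_allele_pathway_means(m, "Bv", ["v"], "RI")
        assert groups[(2,)] == 6 and groups[(0,)] == 6

    def test_null_variant_reproduces_loss_of_function_closed_form(self):
        model, loci = materialize_scenario(3)
        groups = differentiated_allele_pathway_means(model, "B11", loci, "RI")
        # conditional means differ by the unit effect through the chain: a*p
        key2 = tuple(2 if l == "B11.1" else None for l in ["B11.1"])
        diff = groups[(2,)] - groups[(0,)]
        assert diff == 4 * Fraction(1, 2)  # a_B11 * p_T1
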