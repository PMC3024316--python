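"""Expected QTL parameters implied by a hierarchical pathway.

When loci of a signaling pathway segregate in an ideal biparental
population, classical QTL methodology recovers main additive effects
and additive×additive epistatic effects whose expectations follow
directly from the pathway structure.  Two kinds of statistical epistasis
arise: *type I* from the one-way dependency of downstream loci on their
upstream regulators, and *type II* from the mutual dependency of loci
within one unit.  Loci in different B units — even under the same
regulator — are genetically independent.

Effects are defined as orthogonal contrasts on the exhaustively
enumerated expected population (no estimator noise): code the two
homozygote classes at each locus of a subset as ±1, heterozygotes 0,
and take ``β = E[φ·X] / E[φ²]`` where ``φ`` is the product coding.  A
single closed form covers every order ``k``:

    effect(subset) = Σ_B  a_B · (1/2)^k · Π_{other segregating chain loci} p

summed over B units whose regulator chain contains every subset locus,
with ``p`` the functional-genotype frequency of a chain locus — 1/2 in
RI (DH) or under additivity, 3/4 in an F2 under complete dominance.
Setting ``k = 1`` gives the main effect (half the unit effect when
nothing else segregates); the RI identity ``l = A(downstream)`` and the
F2-dominance ``2/3`` cascade across epistasis orders both fall out of
the ``(1/2)/p`` ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations, product
from typing import Mapping, Sequence

from .model import (GeneActionMode, PathwayModel, ScenarioSpec,
                    materialize_scenario, _effective_mode)
from .population import PopulationTable, PopulationType, population_moments

__all__ = [
    "FDCount",
    "count_parameters",
    "classify_subset",
    "expected_main_effect",
    "expected_epistasis",
    "closed_form_effect",
    "closed_form_main_effect",
    "functional_genotype_frequency",
    "pathway_effect_from_qtl",
    "variance_decomposition",
    "predict_genotype_value",
    "differentiated_allele_pathway_means",
]


# ---------------------------------------------------------------------------
# Functional-dependency parameter accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FDCount:
    """Number of expected genetic parameters for a segregation layout."""

    n_main: int
    n_type1: int
    n_type2: int

    @property
    def n1(self) -> int:
        return self.n_main + self.n_type1 + self.n_type2


def classify_subset(model: PathwayModel, loci: Sequence[str]) -> str | None:
    """Epistasis class of a locus subset: ``"II"`` (one unit), ``"I"``
    (units totally ordered along one regulator chain), or ``None``
    (independent loci; e.g. two different B units or two T subtrees)."""
    units = {model.loci[l].unit_id for l in loci}
    if len(units) == 1:
        return "II" if len(loci) >= 2 else None
    for cand in units:
        if units.issubset(set(model.chain(cand))):
            return "I"
    return None


def count_parameters(scenario: int | ScenarioSpec | None = None,
                     model: PathwayModel | None = None,
                     loci: Sequence[str] | None = None) -> FDCount:
    """Count main-effect and type I/II epistatic parameters.

    Either pass one of the seven canonical scenarios, or an explicit
    model plus its segregating loci.  Enumeration is over all locus
    subsets of size ≥ 2, classified by their position in the hierarchy.
    """
    if scenario is not None:
        model, loci = materialize_scenario(scenario, model)
    if model is None or loci is None:
        raise ValueError("need a scenario or an explicit model + loci")
    n1 = n2 = 0
    for k in range(2, len(loci) + 1):
        for sub in combinations(loci, k):
            cls = classify_subset(model, sub)
            if cls == "I":
                n1 += 1
            elif cls == "II":
                n2 += 1
    return FDCount(n_main=len(loci), n_type1=n1, n_type2=n2)


# ---------------------------------------------------------------------------
# Orthogonal-contrast effects on enumerated populations
# ---------------------------------------------------------------------------

def _z(state: int) -> int:
    # additive coding: hom functional +1, het 0, hom null -1
    return state - 1


def contrast_effect(table: PopulationTable, loci: Sequence[str]) -> Fraction:
    """Orthogonal-contrast effect of a locus subset on an enumerated table.

    ``β = E[φX]/E[φ²]`` with ``φ = Π z_j``; for a single locus this is
    half the difference between the homozygote-class marginal means, for
    an RI pair the familiar ``l = ¼[μ(++) − μ(+−) − μ(−+) + μ(−−)]``.
    """
    idx = [table.locus_index(l) for l in loci]
    for l in loci:
        if table.marginal_frequency(l, 2) in (0, 1):
            raise ValueError(f"locus {l} is not segregating in the table")
    num = Fraction(0)
    den = Fraction(0)
    for c in table.classes:
        phi = 1
        for i in idx:
            phi *= _z(c.states[i])
        num += c.frequency * phi * c.value
        den += c.frequency * phi * phi
    return num / den


def expected_main_effect(table: PopulationTable, locus: str) -> Fraction:
    """Expected QTL main additive effect A of one segregating locus."""
    return contrast_effect(table, [locus])


def expected_epistasis(table: PopulationTable, loci: Sequence[str]) -> Fraction:
    """Expected additive×additive (or higher-order) epistatic effect."""
    if len(loci) < 2:
        raise ValueError("epistasis needs a subset of size >= 2")
    return contrast_effect(table, loci)


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def functional_genotype_frequency(level: str, population_type: PopulationType,
                                  mode: GeneActionMode) -> Fraction:
    """Per-locus frequency ``p`` of the functional genotype entering the
    closed forms: 1/2 in RI (DH); in an F2, 3/4 where the locus acts
    dominantly and 1/2 where it acts additively."""
    if population_type == "RI":
        return Fraction(1, 2)
    return Fraction(3, 4) if _effective_mode(level, mode) == "D" else Fraction(1, 2)


def closed_form_effect(model: PathwayModel, loci: Sequence[str],
                       subset: Sequence[str], population_type: PopulationType,
                       mode: GeneActionMode) -> Fraction:
    """Closed-form expectation of the contrast effect of ``subset``.

    Must equal :func:`contrast_effect` on the enumerated population for
    every scenario × population type × gene action (the oracle identity
    tested in the suite).
    """
    seg = set(loci)
    k = len(subset)
    total = Fraction(0)
    for b in model.b_units():
        chain_units = model.chain(b.id)
        chain_loci = [l for u in chain_units for l in model.units[u].loci if l in seg]
        if not set(subset).issubset(chain_loci):
            continue
        if any(model.units[u].fixed_state == "null" for u in chain_units):
            continue
        term = Fraction(b.effect) * Fraction(1, 2 ** k)
        for l in chain_loci:
            if l in subset:
                continue
            term *= functional_genotype_frequency(
                model.units[model.loci[l].unit_id].level, population_type, mode)
        total += term
    return total


def closed_form_main_effect(model: PathwayModel, loci: Sequence[str], locus: str,
                            population_type: PopulationType,
                            mode: GeneActionMode) -> Fraction:
    """Theorem-style closed form for a main effect (``k = 1`` case)."""
    return closed_form_effect(model, loci, [locus], population_type, mode)


def pathway_effect_from_qtl(effect: Fraction | float,
                            context_levels: Sequence[str],
                            population_type: PopulationType,
                            mode: GeneActionMode = "D",
                            order: int = 1,
                            co_adapted: bool = False) -> Fraction:
    """Invert the closed form: pathway effect ``a`` from a QTL parameter.

    ``context_levels`` lists the levels of the *other* segregating loci
    on the unit's chain (upstream regulators plus same-unit partners not
    in the contrast).  For a co-adapted pair detected only through
    epistasis, ``a = 2·l``.
    """
    if co_adapted:
        return 2 * Fraction(effect)
    denom = Fraction(1, 2 ** order)
    for lvl in context_levels:
        denom *= functional_genotype_frequency(lvl, population_type, mode)
    if denom == 0:
        raise ZeroDivisionError("upstream context leaves no functional genotypes")
    return Fraction(effect) / denom


# ---------------------------------------------------------------------------
# Variance decomposition and genotype-value prediction
# ---------------------------------------------------------------------------

def variance_decomposition(table: PopulationTable, model: PathwayModel,
                           ) -> tuple[dict[tuple[str, ...], tuple[Fraction, Fraction]], Fraction]:
    """Portions of the genotypic variance carried by each orthogonal term.

    Returns ``({subset: (effect, share)}, residual_share)``; terms are
    all main effects plus every type-I/II subset.  In an RI population
    the terms are a complete orthogonal basis and the residual is zero;
    in an F2 under dominance, dominance deviations remain in the
    residual.
    """
    _, var = population_moments(table)
    if var == 0:
        raise ValueError("population has zero genotypic variance")
    terms: list[tuple[str, ...]] = [(l,) for l in table.loci]
    for k in range(2, len(table.loci) + 1):
        for sub in combinations(table.loci, k):
            if classify_subset(model, sub) in ("I", "II"):
                terms.append(sub)
    out: dict[tuple[str, ...], tuple[Fraction, Fraction]] = {}
    explained = Fraction(0)
    for sub in terms:
        beta = contrast_effect(table, sub)
        e_phi2 = Fraction(1)
        for l in sub:
            i = table.locus_index(l)
            e_phi2 *= sum((c.frequency * _z(c.states[i]) ** 2 for c in table.classes),
                          Fraction(0))
        share = beta ** 2 * e_phi2 / var
        out[tuple(sub)] = (beta, share)
        explained += share
    return out, 1 - explained


def predict_genotype_value(table: PopulationTable, genotype: Mapping[str, int],
                           convention: str = "model2") -> Fraction:
    """Predicted trait value of a (partial) multilocus genotype.

    ``"model2"`` returns the conditional population mean given the fixed
    states — the pathway model's own expectation.  ``"classical"``
    reconstructs the value from the fitted biometrical terms: population
    mean plus the main and epistatic contrasts among the fixed loci.  In
    an RI population the two coincide; in an F2 under dominance the
    classical additive×additive reconstruction overestimates.
    """
    if convention == "model2":
        return table.conditional_mean(dict(genotype))
    if convention != "classical":
        raise ValueError(f"unknown convention {convention!r}")
    mean, _ = population_moments(table)
    fixed = list(genotype)
    value = mean
    for k in range(1, len(fixed) + 1):
        for sub in combinations(fixed, k):
            beta = contrast_effect(table, sub)
            phi = 1
            for l in sub:
                phi *= _z(genotype[l])
            value += beta * phi
    return value


def differentiated_allele_pathway_means(model: PathwayModel, unit_id: str,
                                        loci: Sequence[str],
                                        population_type: PopulationType,
                                        mode: GeneActionMode = "D",
                                        ) -> dict[tuple[int, ...], Fraction]:
    """Mean trait contribution of each homozygous allele combination at a
    unit carrying functionally differentiated alleles.

    Enumerates the population and returns the conditional trait mean for
    every fully homozygous combination of the unit's segregating loci
    (states 2 = variant-0 homozygote, 0 = variant-1 homozygote).  With
    equal variant weights the groups collapse to the fixed-functional
    value; with one null variant they reproduce the loss-of-function
    closed forms.
    """
    from .population import enumerate_population
    table = enumerate_population(model, loci, population_type, mode)
    unit_loci = [l for l in loci if model.loci[l].unit_id == unit_id]
    out: dict[tuple[int, ...], Fraction] = {}
    for states in product((2, 0), repeat=len(unit_loci)):
        cond = dict(zip(unit_loci, states))
        out[states] = table.conditional_mean(cond)
    return out
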