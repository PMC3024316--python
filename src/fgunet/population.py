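"""Exact enumeration of ideal F2 and RI (DH) populations.

Populations are "ideal": segregating loci are unlinked, allele
frequencies are 1/2, multilocus genotypes occur at exact
Hardy–Weinberg/linkage-equilibrium frequencies, and trait values have
full penetrance.  Everything here is an expectation computed by
exhaustive enumeration with rational arithmetic — there is no sampling.

The heterosis analysis enumerates every way the functional alleles of
the segregating loci can be distributed between the two parents
(2^(r-1) configurations after removing the parent-swap symmetry),
computes the F1 (all-heterozygous) value, mid-parent heterosis
H_MP = F1 − (P1+P2)/2, and inbreeding depression defined as the signed
change E[F2] − F1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Iterable, Literal, Sequence

import numpy as np

from .model import (GeneActionMode, PathwayModel, ScenarioSpec,
                    materialize_scenario, phenotype_of, scenario_config)

__all__ = [
    "GenotypeClass",
    "PopulationTable",
    "HeterosisRecord",
    "CorrelationResult",
    "enumerate_population",
    "population_moments",
    "trait_distribution",
    "enumerate_parental_configurations",
    "heterosis_analysis",
    "heterosis_depression_correlation",
    "scenario_heterosis",
    "scenario_population",
]

PopulationType = Literal["F2", "RI"]

_F2_FREQ = {0: Fraction(1, 4), 1: Fraction(1, 2), 2: Fraction(1, 4)}
_RI_FREQ = {0: Fraction(1, 2), 2: Fraction(1, 2)}


@dataclass(frozen=True)
class GenotypeClass:
    states: tuple[int, ...]
    frequency: Fraction
    value: Fraction


@dataclass
class PopulationTable:
    """Exhaustive genotype-class table for one enumerated population."""

    population_type: PopulationType
    loci: tuple[str, ...]
    classes: list[GenotypeClass]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum((c.frequency for c in self.classes), Fraction(0))
        if total != 1:
            raise ValueError(f"class frequencies sum to {total}, not 1")

    def __len__(self) -> int:
        return len(self.classes)

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def conditional_mean(self, condition: dict[str, int]) -> Fraction:
        """Frequency-weighted mean trait value given fixed states at some loci."""
        idx = {self.locus_index(l): s for l, s in condition.items()}
        num = Fraction(0)
        den = Fraction(0)
        for c in self.classes:
            if all(c.states[i] == s for i, s in idx.items()):
                num += c.frequency * c.value
                den += c.frequency
        if den == 0:
            raise ValueError(f"condition {condition} has zero probability")
        return num / den

    def marginal_frequency(self, locus: str, state: int) -> Fraction:
        i = self.locus_index(locus)
        return sum((c.frequency for c in self.classes if c.states[i] == state),
                   Fraction(0))

    def functional_allele_frequency(self, locus: str) -> Fraction:
        """Frequency of the functional (index-0) allele at one locus."""
        i = self.locus_index(locus)
        return sum((c.frequency * Fraction(c.states[i], 2) for c in self.classes),
                   Fraction(0))


def _state_freqs(population_type: PopulationType) -> dict[int, Fraction]:
    if population_type == "F2":
        return _F2_FREQ
    if population_type == "RI":
        return _RI_FREQ
    raise ValueError(f"unknown population type {population_type!r}")


def enumerate_population(model: PathwayModel, loci: Sequence[str],
                         population_type: PopulationType,
                         mode: GeneActionMode,
                         max_loci: int = 16) -> PopulationTable:
    """Enumerate all multilocus genotype classes with frequencies and values.

    ``loci`` are the segregating loci; the class count is ``3^r`` for F2
    and ``2^r`` for RI.  Raises for ``r`` beyond ``max_loci``.
    """
    r = len(loci)
    if r > max_loci:
        raise ValueError(f"{r} segregating loci exceed the enumeration cap {max_loci}")
    freqs = _state_freqs(population_type)
    classes = []
    for states in product(sorted(freqs), repeat=r):
        freq = math.prod((freqs[s] for s in states), start=Fraction(1))
        genotype = dict(zip(loci, states))
        classes.append(GenotypeClass(states=states, frequency=freq,
                                     value=phenotype_of(genotype, model, mode)))
    return PopulationTable(population_type=population_type, loci=tuple(loci),
                           classes=classes,
                           provenance={"mode": mode, "model": model.name})


def population_moments(table: PopulationTable) -> tuple[Fraction, Fraction]:
    """Exact frequency-weighted mean and genotypic variance."""
    if not table.classes:
        raise ValueError("empty population table")
    mean = sum((c.frequency * c.value for c in table.classes), Fraction(0))
    msq = sum((c.frequency * c.value ** 2 for c in table.classes), Fraction(0))
    return mean, msq - mean ** 2


def trait_distribution(table: PopulationTable,
                       bin_width: float | None = None) -> dict[Fraction, Fraction]:
    """Frequencies aggregated by trait value (or by bin lower edge)."""
    out: dict[Fraction, Fraction] = {}
    for c in table.classes:
        key = c.value if bin_width is None else Fraction(
            math.floor(c.value / Fraction(bin_width))) * Fraction(bin_width)
        out[key] = out.get(key, Fraction(0)) + c.frequency
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# Heterosis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeterosisRecord:
    configuration: tuple[int, ...]  # per locus: 0 = functional allele in P1
    p1_value: Fraction
    p2_value: Fraction
    f1_value: Fraction
    h_mp: Fraction
    inbreeding_depression: Fraction


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    pooling: str
    degenerate: bool = False


def enumerate_parental_configurations(r: int) -> list[tuple[int, ...]]:
    """All 2^(r-1) distributions of functional alleles between the parents.

    Entry ``0`` at a locus means P1 carries the functional allele.  The
    P1↔P2 swap symmetry is removed by pinning the first locus to P1;
    order is lexicographic, hence deterministic.
    """
    if r < 1:
        return [()]
    return [(0,) + rest for rest in product((0, 1), repeat=r - 1)]


def heterosis_analysis(model: PathwayModel, loci: Sequence[str],
                       mode: GeneActionMode) -> list[HeterosisRecord]:
    """One record per parental configuration of the given segregating loci.

    The F1 is heterozygous at every segregating locus regardless of the
    configuration; the expected F2 mean likewise does not depend on
    which parent contributed which allele, so inbreeding depression
    E[F2] − F1 is constant across configurations of one scenario.
    """
    r = len(loci)
    f1 = phenotype_of(dict.fromkeys(loci, 1), model, mode)
    f2_mean, _ = population_moments(enumerate_population(model, loci, "F2", mode))
    records = []
    for cfg in enumerate_parental_configurations(r):
        p1 = phenotype_of({l: (2 if a == 0 else 0) for l, a in zip(loci, cfg)}, model, mode)
        p2 = phenotype_of({l: (0 if a == 0 else 2) for l, a in zip(loci, cfg)}, model, mode)
        records.append(HeterosisRecord(
            configuration=cfg, p1_value=p1, p2_value=p2, f1_value=f1,
            h_mp=f1 - (p1 + p2) / 2,
            inbreeding_depression=f2_mean - f1))
    return records


def scenario_heterosis(scenario: int | ScenarioSpec, mode: GeneActionMode,
                       model: PathwayModel | None = None) -> list[HeterosisRecord]:
    """Heterosis records for one of the seven canonical scenarios."""
    m, loci = materialize_scenario(scenario, model)
    return heterosis_analysis(m, loci, mode)


def heterosis_depression_correlation(scenarios: Iterable[int | ScenarioSpec],
                                     mode: GeneActionMode,
                                     pooling: str = "case",
                                     model: PathwayModel | None = None,
                                     ) -> CorrelationResult:
    """Pearson correlation between mid-parent heterosis and inbreeding depression.

    ``pooling="case"`` pools the per-configuration (H_MP, E[F2]−F1)
    pairs of all requested scenarios; ``pooling="scenario_mean"``
    correlates the per-scenario means of the two quantities.  A
    degenerate input (either variable without variance — which happens
    under pure additivity, where both are identically zero) is reported
    as such with ``r = nan``.
    """
    if pooling not in ("case", "scenario_mean"):
        raise ValueError(f"unknown pooling {pooling!r}")
    xs: list[float] = []
    ys: list[float] = []
    for scn in scenarios:
        records = scenario_heterosis(scn, mode, model)
        if pooling == "case":
            xs.extend(float(rec.h_mp) for rec in records)
            ys.extend(float(rec.inbreeding_depression) for rec in records)
        else:
            xs.append(float(np.mean([float(rec.h_mp) for rec in records])))
            ys.append(float(np.mean([float(rec.inbreeding_depression) for rec in records])))
    x = np.asarray(xs)
    y = np.asarray(ys)
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return CorrelationResult(r=float("nan"), n=len(x), pooling=pooling,
                                 degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    return CorrelationResult(r=r, n=len(x), pooling=pooling)


def scenario_population(scenario: int | ScenarioSpec,
                        population_type: PopulationType,
                        mode: GeneActionMode,
                        model: PathwayModel | None = None) -> PopulationTable:
    """Convenience: materialize a scenario and enumerate its population."""
    m, loci = materialize_scenario(scenario, model)
    table = enumerate_population(m, loci, population_type, mode)
    idx = scenario.index if isinstance(scenario, ScenarioSpec) else scenario
    table.provenance["scenario"] = idx
    return table
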