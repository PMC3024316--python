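"""Step-wise truncation selection on enumerated populations.

Selection here is a conditional expectation, not a sampling process:
a truncation step keeps the genotype classes whose (fully penetrant)
genotypic value passes the threshold and renormalizes their
frequencies.  From the conditioned table we read off functional-allele
frequency shifts per locus, the population mean and variance, and the
gametic linkage disequilibrium induced among surviving classes.

Gamete frequencies are computed exactly from the conditioned genotype
distribution: RI (DH) classes are themselves gametic, while F2 classes
transmit each allele with probability equal to its dosage, assuming
unlinked loci and random union within the retained set.  This exact
conditional computation replaces iterative approximations, which are
unnecessary at enumeration scale.

Positive trajectories climb the threshold ladder 4, 8, …, 32; negative
trajectories descend 32, 28, …, 4 with the rule flipped to ``value ≤
threshold`` so that successive steps are nested and selection intensity
increases monotonically along the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from typing import Literal

from .population import GenotypeClass, PopulationTable, population_moments

__all__ = [
    "SelectionExhausted",
    "SelectionStep",
    "TrajectoryTable",
    "truncation_select",
    "functional_frequencies",
    "frequency_shifts",
    "gametic_ld",
    "ld_matrix",
    "stepwise_selection_experiment",
]

Direction = Literal["positive", "negative"]


class SelectionExhausted(RuntimeError):
    """Raised when a truncation rule retains no genotype class."""


def truncation_select(table: PopulationTable, direction: Direction,
                      threshold: float | Fraction) -> PopulationTable:
    """Condition the population on passing a trait threshold."""
    thr = Fraction(threshold)
    if direction == "positive":
        kept = [c for c in table.classes if c.value >= thr]
    elif direction == "negative":
        kept = [c for c in table.classes if c.value <= thr]
    else:
        raise ValueError(f"unknown direction {direction!r}")
    total = sum((c.frequency for c in kept), Fraction(0))
    if total == 0:
        raise SelectionExhausted(
            f"no class satisfies value {'>=' if direction == 'positive' else '<='} {thr}")
    classes = [GenotypeClass(c.states, c.frequency / total, c.value) for c in kept]
    prov = dict(table.provenance)
    prov.setdefault("selection", []).append((direction, float(thr)))
    return PopulationTable(table.population_type, table.loci, classes, prov)


def functional_frequencies(table: PopulationTable) -> dict[str, Fraction]:
    """Functional-allele frequency per locus in a (possibly conditioned) table."""
    return {l: table.functional_allele_frequency(l) for l in table.loci}


def frequency_shifts(table: PopulationTable) -> dict[str, Fraction]:
    """Shift of the functional-allele frequency from the unselected 1/2."""
    return {l: f - Fraction(1, 2) for l, f in functional_frequencies(table).items()}


def _gamete_freqs(table: PopulationTable, la: str, lb: str) -> dict[tuple[int, int], Fraction]:
    """Joint gamete frequencies for a locus pair.

    Allele 1 denotes the functional allele; transmission probability per
    class is the allele dosage (state/2), exact for RI classes (already
    homozygous) and the unlinked-loci expectation for F2 classes.
    """
    ia, ib = table.locus_index(la), table.locus_index(lb)
    out = {(1, 1): Fraction(0), (1, 0): Fraction(0),
           (0, 1): Fraction(0), (0, 0): Fraction(0)}
    for c in table.classes:
        da = Fraction(c.states[ia], 2)
        db = Fraction(c.states[ib], 2)
        out[(1, 1)] += c.frequency * da * db
        out[(1, 0)] += c.frequency * da * (1 - db)
        out[(0, 1)] += c.frequency * (1 - da) * db
        out[(0, 0)] += c.frequency * (1 - da) * (1 - db)
    return out


def gametic_ld(table: PopulationTable, la: str, lb: str) -> tuple[Fraction, Fraction | None]:
    """Gametic disequilibrium ``D`` and its normalization ``D'`` for a pair.

    ``D = p(AB) − p(A)p(B)`` on the functional alleles; ``D' = D/D_max``
    with the standard bound.  Returns ``D' = None`` when either locus is
    fixed (undefined).
    """
    g = _gamete_freqs(table, la, lb)
    pa = g[(1, 1)] + g[(1, 0)]
    pb = g[(1, 1)] + g[(0, 1)]
    d = g[(1, 1)] - pa * pb
    if pa in (0, 1) or pb in (0, 1):
        return d, None
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return d, Fraction(0)
    return d, d / dmax


def ld_matrix(table: PopulationTable) -> dict[tuple[str, str], tuple[Fraction, Fraction | None]]:
    """D and D' for every locus pair of the table."""
    return {(a, b): gametic_ld(table, a, b)
            for a, b in combinations(table.loci, 2)}


@dataclass(frozen=True)
class SelectionStep:
    direction: Direction
    threshold: float
    retained_fraction: Fraction
    frequencies: dict[str, Fraction]
    mean: Fraction
    variance: Fraction
    ld: dict[tuple[str, str], tuple[Fraction, Fraction | None]]


@dataclass
class TrajectoryTable:
    direction: Direction
    steps: list[SelectionStep] = field(default_factory=list)
    truncated: bool = False  # selection exhausted before the ladder ended


def stepwise_selection_experiment(table: PopulationTable, direction: Direction,
                                  thresholds: list[float] | None = None,
                                  ) -> TrajectoryTable:
    """Run the full threshold ladder, conditioning cumulatively.

    Each step reports the retained fraction of the *original* population,
    per-locus functional-allele frequencies, moments and the pairwise LD
    matrix.  An exhausted step ends the trajectory early (flagged).
    """
    if thresholds is None:
        thresholds = [4.0 * i for i in range(1, 9)]
        if direction == "negative":
            thresholds = thresholds[::-1]
    traj = TrajectoryTable(direction=direction)
    current = table
    retained = Fraction(1)
    for thr in thresholds:
        try:
            nxt = truncation_select(current, direction, thr)
        except SelectionExhausted:
            traj.truncated = True
            break
        thr_f = Fraction(thr)
        kept = sum((c.frequency for c in current.classes
                    if (c.value >= thr_f if direction == "positive" else c.value <= thr_f)),
                   Fraction(0))
        retained *= kept
        mean, var = population_moments(nxt)
        traj.steps.append(SelectionStep(
            direction=direction, threshold=float(thr),
            retained_fraction=retained,
            frequencies=functional_frequencies(nxt),
            mean=mean, variance=var, ld=ld_matrix(nxt)))
        current = nxt
    return traj
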