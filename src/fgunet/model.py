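"""Hierarchical pathway model: functional genetic units and the genotype→phenotype engine.

A signaling pathway is modelled as a forest of functional genetic units
(FGUs) on three levels: a signal-transduction unit ``S`` at the root,
transcriptional-regulation units ``T`` in the middle, and downstream
biosynthesis units ``B`` that carry the actual trait effects.  All loci
within one unit are mutually required ("house of cards"): the unit is
functional only to the degree that every member locus contributes a
functional product.  Downstream units additionally depend on the
functionality of every regulator above them in the chain, so a ``B``
unit contributes its effect ``a_ij`` to the trait only when its whole
``S → T → B`` chain is functional.

Gene action enters through the per-locus *dosage* of a genotype:

* complete dominance (``D``) — heterozygotes are fully functional;
* additivity (``A``) — heterozygotes carry half the dosage;
* mixed (``DA``) — regulatory ``S``/``T`` loci dominant, ``B`` loci additive.

Multi-locus units and regulator chains combine dosages multiplicatively,
which is the unique rule that (i) reduces to the expected half-unit main
effect for a single segregating locus and (ii) yields exactly zero
mid-parent heterosis whenever no functional dependency segregates.
Repressing regulation inverts the parent factor ``f → 1 - f``.

All arithmetic is done in exact rationals so that population
enumeration downstream is free of floating-point drift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from itertools import product
from typing import Iterable, Mapping

import yaml

__all__ = [
    "Locus",
    "FunctionalGeneticUnit",
    "PathwayModel",
    "GeneActionMode",
    "ScenarioSpec",
    "build_model2",
    "scenario_config",
    "materialize_scenario",
    "unit_dosage",
    "phenotype_of",
    "load_model",
    "save_model",
]

LEVELS = ("S", "T", "B")

#: Gene-action modes: complete dominance, additivity, mixed (S/T dominant, B additive).
GeneActionMode = str
MODES = ("D", "A", "DA")


@dataclass(frozen=True)
class Locus:
    """A biallelic locus belonging to exactly one FGU.

    ``weights`` are the functional contribution of each allele in
    ``[0, 1]``; the default ``(1, 0)`` is the functional/null pair used
    throughout the scenario simulations.  Differentiated functional
    variants get two nonzero weights.
    """

    id: str
    unit_id: str
    alleles: tuple[str, str] = ("F", "o")
    weights: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.alleles) != 2 or len(self.weights) != 2:
            raise ValueError(f"locus {self.id}: exactly two alleles required")
        if not all(0 <= w <= 1 for w in self.weights):
            raise ValueError(f"locus {self.id}: allele weights must lie in [0, 1]")


@dataclass
class FunctionalGeneticUnit:
    """A group of mutually dependent loci at one level of a pathway.

    ``effect`` is the trait contribution of a ``B`` unit when its whole
    chain is functional; for regulatory units it is ignored by the
    engine (their subtree effect is reported instead).  ``fixed_state``
    describes the non-segregating background of the unit: ``"functional"``
    (default) or ``"null"`` (both parents share a crippling mutation, so
    the unit never functions).  ``combination_weights`` optionally maps a
    tuple of per-locus allele indices to a functional weight in [0, 1],
    expressing co-adapted allele complexes that a per-locus weight
    cannot represent.
    """

    id: str
    level: str
    parent: str | None = None
    loci: list[str] = field(default_factory=list)
    effect: float = 0.0
    sign: str = "activating"
    fixed_state: str = "functional"
    combination_weights: dict[tuple[int, ...], float] | None = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unit {self.id}: level must be one of {LEVELS}")
        if self.sign not in ("activating", "repressing"):
            raise ValueError(f"unit {self.id}: unknown regulation sign {self.sign!r}")
        if self.fixed_state not in ("functional", "null"):
            raise ValueError(f"unit {self.id}: unknown fixed state {self.fixed_state!r}")
        if self.effect < 0:
            raise ValueError(f"unit {self.id}: unit effect must be non-negative")


class PathwayModel:
    """A forest of FGUs rooted at ``S`` units, with a locus index."""

    def __init__(self, units: Iterable[FunctionalGeneticUnit], name: str = "pathway"):
        self.name = name
        self.units: dict[str, FunctionalGeneticUnit] = {}
        for u in units:
            if u.id in self.units:
                raise ValueError(f"duplicate unit id {u.id}")
            self.units[u.id] = u
        self.loci: dict[str, Locus] = {}
        for u in self.units.values():
            for lid in u.loci:
                if lid in self.loci:
                    raise ValueError(f"locus {lid} assigned to more than one unit")
                self.loci[lid] = Locus(id=lid, unit_id=u.id)
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        for u in self.units.values():
            if u.parent is not None and u.parent not in self.units:
                raise ValueError(f"unit {u.id}: unknown parent {u.parent}")
            if u.level == "S" and u.parent is not None:
                raise ValueError(f"S unit {u.id} cannot have a parent")
        for u in self.units.values():
            chain = self.chain(u.id)
            levels = [self.units[c].level for c in chain]
            if u.level == "B" and levels != ["B", "T", "S"]:
                raise ValueError(f"B unit {u.id}: chain to root must pass one T and one S")
            if u.level == "T" and levels != ["T", "S"]:
                raise ValueError(f"T unit {u.id}: parent must be an S unit")

    def chain(self, unit_id: str) -> list[str]:
        """Unit ids from ``unit_id`` up to its root, inclusive."""
        out = [unit_id]
        seen = {unit_id}
        while (p := self.units[out[-1]].parent) is not None:
            if p in seen:
                raise ValueError(f"cycle in unit hierarchy at {p}")
            out.append(p)
            seen.add(p)
        return out

    def children(self, unit_id: str) -> list[str]:
        return [u.id for u in self.units.values() if u.parent == unit_id]

    def b_units(self) -> list[FunctionalGeneticUnit]:
        return [u for u in self.units.values() if u.level == "B"]

    def subtree_effect(self, unit_id: str) -> float:
        """Summed ``B`` effects below (and including) a unit, for reporting."""
        u = self.units[unit_id]
        if u.level == "B":
            return u.effect
        return sum(self.subtree_effect(c) for c in self.children(unit_id))

    def max_value(self) -> float:
        return sum(b.effect for b in self.b_units())

    def add_locus(self, locus: Locus) -> None:
        if locus.id in self.loci:
            raise ValueError(f"duplicate locus {locus.id}")
        if locus.unit_id not in self.units:
            raise ValueError(f"locus {locus.id}: unknown unit {locus.unit_id}")
        self.loci[locus.id] = locus
        self.units[locus.unit_id].loci.append(locus.id)

    def copy(self) -> "PathwayModel":
        units = [
            replace(u, loci=list(u.loci),
                    combination_weights=dict(u.combination_weights) if u.combination_weights else None)
            for u in self.units.values()
        ]
        m = PathwayModel.__new__(PathwayModel)
        m.name = self.name
        m.units = {u.id: u for u in units}
        m.loci = dict(self.loci)
        return m


@dataclass(frozen=True)
class ScenarioSpec:
    """Per-unit segregating-locus counts plus fixed-null flags for one scenario."""

    index: int
    seg_counts: tuple[tuple[str, int], ...]
    fixed_null: frozenset[str] = frozenset()

    @property
    def r(self) -> int:
        return sum(n for _, n in self.seg_counts)

    def counts(self) -> dict[str, int]:
        return dict(self.seg_counts)


# ---------------------------------------------------------------------------
# The canonical nine-unit pathway and the seven segregation scenarios
# ---------------------------------------------------------------------------

_MODEL2_B_EFFECTS = {
    ("B11", "T1"): 4.0, ("B12", "T1"): 8.0, ("B13", "T1"): 4.0,
    ("B21", "T2"): 8.0, ("B22", "T2"): 4.0, ("B23", "T2"): 4.0,
}

_SCENARIOS: dict[int, tuple[dict[str, int], frozenset[str]]] = {
    1: ({"T1": 1, "T2": 1}, frozenset({"B23"})),
    2: ({"B11": 1, "B13": 1, "B21": 1, "B23": 1}, frozenset()),
    3: ({"T1": 1, "B11": 1, "B13": 1, "T2": 1, "B21": 1, "B23": 1}, frozenset()),
    4: ({"S": 1, "T1": 1, "B11": 1, "B13": 1, "T2": 1, "B21": 1, "B23": 1}, frozenset()),
    5: ({"S": 1, "T1": 2, "T2": 3}, frozenset()),
    6: ({"T1": 1, "B11": 2, "T2": 1, "B21": 3}, frozenset()),
    7: ({"B12": 1, "B13": 1, "T2": 1, "B21": 3, "B22": 1, "B23": 1}, frozenset()),
}


def build_model2() -> PathwayModel:
    """The canonical single-pathway model: 1 S, 2 T and 6 B units.

    The B effects are (4, 8, 4) under T1 and (8, 4, 4) under T2, for a
    maximum pathway value of 32 when every unit is functional.
    """
    units = [FunctionalGeneticUnit("S", "S"),
             FunctionalGeneticUnit("T1", "T", parent="S"),
             FunctionalGeneticUnit("T2", "T", parent="S")]
    units += [FunctionalGeneticUnit(b, "B", parent=t, effect=a)
              for (b, t), a in _MODEL2_B_EFFECTS.items()]
    return PathwayModel(units, name="model2")


def scenario_config(k: int) -> ScenarioSpec:
    """Segregating-locus counts for scenario ``k`` (1..7)."""
    if k not in _SCENARIOS:
        raise ValueError(f"scenario index must be in 1..7, got {k}")
    counts, fixed_null = _SCENARIOS[k]
    return ScenarioSpec(index=k, seg_counts=tuple(counts.items()), fixed_null=fixed_null)


def materialize_scenario(scenario: ScenarioSpec | int,
                         model: PathwayModel | None = None) -> tuple[PathwayModel, list[str]]:
    """Attach the scenario's segregating loci to a copy of the model.

    Returns the model copy and the ordered segregating-locus ids; locus
    ids are ``<unit>.<k>``.  Fixed-null units carry one shared mutant
    locus in both parents and never function.
    """
    if isinstance(scenario, int):
        scenario = scenario_config(scenario)
    model = (model or build_model2()).copy()
    loci: list[str] = []
    for uid, n in scenario.seg_counts:
        for i in range(1, n + 1):
            lid = f"{uid}.{i}"
            model.add_locus(Locus(id=lid, unit_id=uid))
            loci.append(lid)
    for uid in scenario.fixed_null:
        model.units[uid].fixed_state = "null"
    return model, loci


# ---------------------------------------------------------------------------
# Genotype evaluation
# ---------------------------------------------------------------------------

def _effective_mode(level: str, mode: GeneActionMode) -> str:
    if mode not in MODES:
        raise ValueError(f"unknown gene action mode {mode!r}")
    if mode == "DA":
        return "D" if level in ("S", "T") else "A"
    return mode


def _locus_dosage(state: int, weights: tuple[float, float], mode: str) -> Fraction:
    """Dosage of a genotype at one locus; ``state`` counts copies of allele 0."""
    if state not in (0, 1, 2):
        raise ValueError(f"unknown locus state {state!r}")
    w0, w1 = Fraction(weights[0]), Fraction(weights[1])
    if mode == "D":
        return w0 if state == 2 else (w1 if state == 0 else max(w0, w1))
    return (state * w0 + (2 - state) * w1) / 2


def unit_dosage(genotype: Mapping[str, int], unit: FunctionalGeneticUnit,
                model: PathwayModel, mode: GeneActionMode) -> Fraction:
    """Functional factor of one unit in ``[0, 1]`` (its own loci only).

    Under dominance this is 1 iff every member locus carries at least
    one functional allele; under additivity it is the product of the
    per-locus half-dosages.  Loci absent from ``genotype`` are the
    non-segregating background and contribute the unit's fixed state.
    """
    if unit.fixed_state == "null":
        return Fraction(0)
    lmode = _effective_mode(unit.level, mode)
    if unit.combination_weights is not None:
        return _combination_dosage(genotype, unit, lmode)
    d = Fraction(1)
    for lid in unit.loci:
        state = genotype.get(lid)
        if state is None:
            continue
        d *= _locus_dosage(state, model.loci[lid].weights, lmode)
    return d


def _combination_dosage(genotype: Mapping[str, int], unit: FunctionalGeneticUnit,
                        lmode: str) -> Fraction:
    """Dosage of a unit whose function is defined per allele combination.

    Heterozygous loci are expanded over their two alleles: additivity
    averages the weight over the 2^h phase combinations (the gamete-level
    mean), dominance takes the best combination.
    """
    states = [genotype.get(lid, 2) for lid in unit.loci]
    choices = [(0,) if s == 2 else (1,) if s == 0 else (0, 1) for s in states]
    weights = [Fraction(unit.combination_weights.get(combo, 0.0))
               for combo in product(*choices)]
    if lmode == "D":
        return max(weights)
    return sum(weights, Fraction(0)) / len(weights)


def _reach(unit_id: str, genotype: Mapping[str, int], model: PathwayModel,
           mode: GeneActionMode, cache: dict[str, Fraction]) -> Fraction:
    """Chain-effective functionality of a unit: own gate times the (possibly
    inverted) reach of its parent."""
    if unit_id in cache:
        return cache[unit_id]
    unit = model.units[unit_id]
    f = unit_dosage(genotype, unit, model, mode)
    if unit.parent is not None:
        pf = _reach(unit.parent, genotype, model, mode, cache)
        f *= (1 - pf) if unit.sign == "repressing" else pf
    cache[unit_id] = f
    return f


def phenotype_of(genotype: Mapping[str, int], model: PathwayModel,
                 mode: GeneActionMode) -> Fraction:
    """Genotypic trait value: sum of B-unit effects weighted by chain reach.

    Deterministic, 100% penetrance; the result lies in ``[0, Σ a_ij]``.
    """
    cache: dict[str, Fraction] = {}
    total = Fraction(0)
    for b in model.b_units():
        total += Fraction(b.effect) * _reach(b.id, genotype, model, mode, cache)
    return total


# ---------------------------------------------------------------------------
# Serialization (YAML/JSON round trip)
# ---------------------------------------------------------------------------

def _model_to_dict(model: PathwayModel) -> dict:
    units = []
    for u in model.units.values():
        d: dict = {"id": u.id, "level": u.level, "parent": u.parent,
                   "loci": list(u.loci), "effect": u.effect, "sign": u.sign,
                   "fixed_state": u.fixed_state}
        if u.combination_weights:
            d["combination_weights"] = {
                ",".join(map(str, k)): v for k, v in u.combination_weights.items()}
        units.append(d)
    loci = [{"id": l.id, "unit": l.unit_id, "alleles": list(l.alleles),
             "weights": list(l.weights)} for l in model.loci.values()]
    return {"name": model.name, "units": units, "loci": loci}


def _model_from_dict(data: dict) -> PathwayModel:
    units = []
    for d in data["units"]:
        cw = d.get("combination_weights")
        units.append(FunctionalGeneticUnit(
            id=d["id"], level=d["level"], parent=d.get("parent"),
            loci=[], effect=float(d.get("effect", 0.0)),
            sign=d.get("sign", "activating"),
            fixed_state=d.get("fixed_state", "functional"),
            combination_weights={tuple(int(x) for x in k.split(",")): float(v)
                                 for k, v in cw.items()} if cw else None,
        ))
    model = PathwayModel(units, name=data.get("name", "pathway"))
    for l in data.get("loci", []):
        model.add_locus(Locus(id=l["id"], unit_id=l["unit"],
                              alleles=tuple(l.get("alleles", ("F", "o"))),
                              weights=tuple(l.get("weights", (1.0, 0.0)))))
    return model


def save_model(model: PathwayModel, path: str) -> None:
    data = _model_to_dict(model)
    with open(path, "w", encoding="utf-8") as fh:
        if str(path).endswith(".json"):
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def load_model(path: str) -> PathwayModel:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
    return _model_from_dict(data)
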