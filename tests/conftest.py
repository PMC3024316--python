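"""Shared fixtures: canonical models, co-adapted units, planted cohorts."""

from __future__ import annotations

import pytest

from fgunet.model import FunctionalGeneticUnit, Locus, PathwayModel, build_model2


@pytest.fixture(scope="session")
def model2() -> PathwayModel:
    return build_model2()


@pytest.fixture(scope="session")
def co_adapted_model() -> PathwayModel:
    """One B unit whose two loci form co-adapted allele complexes:
    parental combinations function (effect 4), recombinants do not."""
    units = [
        FunctionalGeneticUnit("S", "S"),
        FunctionalGeneticUnit("T1", "T", parent="S"),
        FunctionalGeneticUnit("Bc", "B", parent="T1", effect=4.0,
                              combination_weights={(0, 0): 1.0, (1, 1): 1.0,
                                                   (0, 1): 0.0, (1, 0): 0.0}),
    ]
    m = PathwayModel(units, name="co-adapted")
    m.add_locus(Locus("A", "Bc"))
    m.add_locus(Locus("B", "Bc"))
    return m


def three_branch_model() -> PathwayModel:
    """Three redundant two-locus B units: the flat planted network."""
    units = [FunctionalGeneticUnit("S", "S"),
             FunctionalGeneticUnit("T1", "T", parent="S")]
    units += [FunctionalGeneticUnit(f"D{i}", "B", parent="T1", effect=4.0)
              for i in (1, 2, 3)]
    m = PathwayModel(units, name="planted-three-branch")
    for i in (1, 2, 3):
        m.add_locus(Locus(f"d{i}a", f"D{i}"))
        m.add_locus(Locus(f"d{i}b", f"D{i}"))
    return m


def layered_model() -> PathwayModel:
    """A two-locus upstream unit required by two redundant single-locus
    downstream units: the layered planted network."""
    units = [FunctionalGeneticUnit("S", "S"),
             FunctionalGeneticUnit("U", "T", parent="S"),
             FunctionalGeneticUnit("D1", "B", parent="U", effect=4.0),
             FunctionalGeneticUnit("D2", "B", parent="U", effect=4.0)]
    m = PathwayModel(units, name="planted-layered")
    m.add_locus(Locus("u1", "U"))
    m.add_locus(Locus("u2", "U"))
    m.add_locus(Locus("d1", "D1"))
    m.add_locus(Locus("d2", "D2"))
    return m
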