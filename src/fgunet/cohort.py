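"""Synthetic backcross-derived cohorts with a planted genetic network.

Emulates the shape of a selective-introgression experiment: a large
BC₃F₂ population genotyped at a marker panel in which a subset of
markers tags the loci of a planted hierarchical pathway conferring
survival of a stress treatment, and the remainder are neutral
background markers.  Lines are drawn with independent per-locus
genotypes at the exact neutral frequencies of the scheme (loci are
unlinked; an optional bin map creates perfectly linked marker clusters
to exercise redundancy removal).  Donor alleles are the functional
alleles of the planted network; survival is evaluated on the fully
penetrant genotypic trait value.

Defaults mirror the emulated study's shape: 1,900 lines and a panel of
~160 markers under a BC₃F₂ scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .il_network import (IntrogressionExpectation, construct_network,
                         detect_fgus, expected_introgression)
from .model import PathwayModel, phenotype_of

__all__ = [
    "CohortSpec",
    "CohortOutput",
    "simulate_bc_population",
    "select_survivors",
    "end_to_end_recovery",
]


@dataclass
class CohortSpec:
    """Design of one synthetic cohort.

    ``survival_threshold`` is the minimum genotypic trait value a line
    must express to survive; with the dominance engine and a planted
    network of positive effects, any threshold > 0 means "at least one
    complete functional branch".  ``model=None`` plants nothing (a null
    cohort).
    """

    model: PathwayModel | None
    n_lines: int = 1900
    n_neutral_markers: int = 160
    n_backcross: int = 3
    n_self: int = 1
    survival_threshold: float = 1e-9
    mode: str = "D"
    seed: int = 0
    bins: dict[str, str] = field(default_factory=dict)

    @property
    def network_markers(self) -> list[str]:
        return sorted(self.model.loci) if self.model is not None else []


@dataclass
class CohortOutput:
    spec: CohortSpec
    expectation: IntrogressionExpectation
    genotypes: pd.DataFrame        # lines × markers, codes 0/1/2
    trait_values: pd.Series
    survivors: pd.DataFrame | None = None


def simulate_bc_population(spec: CohortSpec) -> CohortOutput:
    """Draw the pre-selection cohort.

    Genotypes are i.i.d. per line × marker at the scheme's exact
    neutral genotype frequencies; trait values come from the pathway
    engine with donor alleles as the functional alleles.  Byte-identical
    under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    exp = expected_introgression(spec.n_backcross, spec.n_self)
    probs = [float(f) for f in exp.genotype_frequencies]
    markers = spec.network_markers + [f"n{i:03d}" for i in range(spec.n_neutral_markers)]
    geno = rng.choice([0, 1, 2], size=(spec.n_lines, len(markers)), p=probs)
    frame = pd.DataFrame(geno, columns=markers,
                         index=[f"L{i:05d}" for i in range(spec.n_lines)])
    for marker, source in spec.bins.items():
        if marker in frame.columns and source in frame.columns and marker != source:
            frame[marker] = frame[source]  # perfectly linked cluster member
    if spec.model is None:
        traits = pd.Series(0.0, index=frame.index)
    else:
        net = spec.network_markers
        traits = frame[net].apply(
            lambda row: float(phenotype_of(row.to_dict(), spec.model, spec.mode)),
            axis=1)
    return CohortOutput(spec=spec, expectation=exp, genotypes=frame,
                       trait_values=traits)


def select_survivors(cohort: CohortOutput,
                     rule: Callable[[pd.Series], pd.Series] | None = None,
                     n_random: int | None = None) -> pd.DataFrame:
    """Apply the survival rule and return the survivor genotype matrix.

    The default rule keeps lines whose trait value reaches the spec's
    threshold.  ``n_random`` instead draws that many survivors at
    random, independent of genotype — the null experiment.
    """
    if n_random is not None:
        rng = np.random.default_rng(cohort.spec.seed + 1)
        idx = rng.choice(cohort.genotypes.index, size=n_random, replace=False)
        survivors = cohort.genotypes.loc[sorted(idx)]
    else:
        mask = (rule(cohort.trait_values) if rule is not None
                else cohort.trait_values >= cohort.spec.survival_threshold)
        survivors = cohort.genotypes.loc[mask]
    if len(survivors) == 0:
        raise RuntimeError("no line satisfies the survival rule")
    cohort.survivors = survivors
    return survivors


def end_to_end_recovery(cohort: CohortOutput, alpha: float = 1e-4,
                        max_mismatch: int | None = None) -> dict:
    """Run the detection arm on the survivors and score it against the truth.

    Reports the detected FGU calls, which planted multi-locus units were
    recovered as AGs (all members grouped together), precision/recall of
    planted-locus detection, false positives among neutral markers, and
    whether the network's group structure separates the planted branches
    without spurious inclusion edges between them.
    """
    if cohort.survivors is None:
        raise ValueError("select survivors before scoring recovery")
    calls = detect_fgus(cohort.survivors, cohort.expectation, alpha=alpha,
                        bins=cohort.spec.bins or None, max_mismatch=max_mismatch)
    network = construct_network(calls, cohort.survivors)
    spec = cohort.spec
    planted_units = ({u.id: tuple(sorted(u.loci)) for u in spec.model.units.values()
                      if u.loci} if spec.model is not None else {})
    detected_loci = {l for c in calls for l in c.loci}
    planted_loci = set(spec.network_markers)
    ag_members = {frozenset(c.loci) for c in calls if c.kind == "AG"}
    recovered_ags = {uid: frozenset(loci) in ag_members
                     for uid, loci in planted_units.items() if len(loci) >= 2}
    neutral_fp = sorted(detected_loci - planted_loci)
    tp = len(detected_loci & planted_loci)
    return {
        "calls": calls,
        "network": network,
        "recovered_ags": recovered_ags,
        "all_multilocus_recovered": all(recovered_ags.values()) if recovered_ags else None,
        "precision": tp / len(detected_loci) if detected_loci else None,
        "recall": tp / len(planted_loci) if planted_loci else None,
        "false_positive_neutral": neutral_fp,
        "n_tests": cohort.survivors.shape[1],
        "n_survivors": len(cohort.survivors),
    }
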