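"""Network detection from selected introgression lines.

The population-genetics detection arm works on a matrix of selected
lines × markers with codes 0 (recipient homozygote), 1 (heterozygote),
2 (donor homozygote).  Against the neutral expectation of a backcross/
selfing scheme it applies:

* per-locus χ² goodness-of-fit tests of allelic and genotypic
  frequencies (excess introgression at loci under selection);
* the multilocus association-group (AG) probability
  ``P = P_i^m · (1 − P_i)^(n−m)`` for ``m`` of ``n`` lines sharing a
  co-introgression at unlinked loci, applied to each of the
  ``r(r−1)/2`` pairs of a candidate group;
* pairwise gametic LD (``D``, ``D'``) on donor-carrier coding;
* hierarchical network construction: positively associated FGUs form
  groups, and within a group an FGU whose carriers are contained in
  another's is layered below it (progressively reduced, inclusive
  introgression).

The default neutral scheme is BC₃F₂: donor allele frequency 1/16,
carrier (introgression) frequency P_i = 3/32.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntrogressionExpectation",
    "FGUCall",
    "expected_introgression",
    "carrier_sets",
    "single_locus_excess_test",
    "ag_probability",
    "ag_probability_test",
    "ld_prime",
    "collapse_linked_loci",
    "detect_fgus",
    "construct_network",
]


@dataclass(frozen=True)
class IntrogressionExpectation:
    """Neutral expectations for a k-backcross, m-self scheme."""

    n_backcross: int
    n_self: int
    allele_frequency: Fraction
    genotype_frequencies: tuple[Fraction, Fraction, Fraction]  # (rec hom, het, donor hom)

    @property
    def carrier_frequency(self) -> Fraction:
        return self.genotype_frequencies[1] + self.genotype_frequencies[2]


def expected_introgression(n_backcross: int = 3, n_self: int = 1) -> IntrogressionExpectation:
    """Exact neutral donor frequencies for a BC_k F_(m+1) scheme.

    Each backcross halves the heterozygous fraction (no donor
    homozygotes can arise); each selfing generation halves it again
    while converting a quarter of it to donor homozygotes.
    """
    if n_backcross < 0 or n_self < 0:
        raise ValueError("generation counts must be non-negative")
    het = Fraction(1, 2 ** n_backcross)  # BC_k F_1
    donor_hom = Fraction(0)
    for _ in range(n_self):
        donor_hom += het / 4
        het /= 2
    q = het / 2 + donor_hom
    return IntrogressionExpectation(
        n_backcross=n_backcross, n_self=n_self, allele_frequency=q,
        genotype_frequencies=(1 - het - donor_hom, het, donor_hom))


def carrier_sets(matrix: pd.DataFrame) -> dict[str, frozenset]:
    """Lines carrying at least one donor allele, per marker."""
    return {m: frozenset(matrix.index[matrix[m] >= 1]) for m in matrix.columns}


def single_locus_excess_test(matrix: pd.DataFrame, locus: str,
                             expectation: IntrogressionExpectation,
                             kind: str = "genotypic",
                             min_calls: int = 5) -> tuple[float, float]:
    """χ² goodness-of-fit of observed donor frequencies vs the neutral scheme.

    ``kind``: ``"genotypic"`` (three genotype classes), ``"allelic"``
    (allele counts) or ``"carrier"`` (carrier vs non-carrier).  Returns
    ``(statistic, p_value)``.
    """
    col = matrix[locus].dropna().astype(int)
    n = len(col)
    if n < min_calls:
        raise ValueError(f"locus {locus}: only {n} non-missing calls")
    counts = np.array([(col == 0).sum(), (col == 1).sum(), (col == 2).sum()], float)
    g = expectation.genotype_frequencies
    if kind == "genotypic":
        obs, exp = counts, np.array([float(f) * n for f in g])
    elif kind == "allelic":
        q = float(expectation.allele_frequency)
        obs = np.array([2 * counts[0] + counts[1], counts[1] + 2 * counts[2]])
        exp = np.array([(1 - q) * 2 * n, q * 2 * n])
    elif kind == "carrier":
        p = float(expectation.carrier_frequency)
        obs = np.array([counts[0], counts[1] + counts[2]])
        exp = np.array([(1 - p) * n, p * n])
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    stat = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return stat, float(stats.chi2.sf(stat, df))


def ag_probability(p_i: float, n: int, m: int) -> float:
    """Probability of ``m`` of ``n`` lines sharing a co-introgression at
    unlinked loci of neutral carrier frequency ``p_i``:
    ``P = p_i^m (1 − p_i)^(n−m)`` (the two extreme terms of the binomial
    law, hence a lower bound on the exact binomial tail)."""
    if not 0 <= m <= n:
        raise ValueError("need 0 <= m <= n")
    return float(p_i) ** m * (1.0 - float(p_i)) ** (n - m)


def ag_probability_test(matrix: pd.DataFrame, loci: list[str],
                        expectation: IntrogressionExpectation,
                        max_mismatch: int | None = None) -> dict:
    """Association-group test for a set of (genetically unlinked) loci.

    Co-introgression carriers are lines carrying the donor at *every*
    member locus.  The AG probability is evaluated for each of the
    ``r(r−1)/2`` pairwise associations; the group value reported is the
    pair maximum (the weakest pair decides).  ``perfect`` records exact
    carrier-set equality across members; ``max_mismatch`` (lines allowed
    to differ between any two carrier sets) relaxes the perfect-
    association requirement for noisy data, default none required.
    """
    if len(loci) < 2:
        raise ValueError("an association group needs at least two loci")
    sets = carrier_sets(matrix[loci])
    n = len(matrix)
    p_i = float(expectation.carrier_frequency)
    pair_p = {}
    mismatches = {}
    for a, b in combinations(loci, 2):
        m = len(sets[a] & sets[b])
        pair_p[(a, b)] = ag_probability(p_i, n, m)
        mismatches[(a, b)] = len(sets[a] ^ sets[b])
    co_carriers = frozenset.intersection(*sets.values())
    perfect = all(v == 0 for v in mismatches.values())
    compatible = perfect if max_mismatch is None else all(
        v <= max_mismatch for v in mismatches.values())
    return {"loci": tuple(loci), "m": len(co_carriers), "n": n,
            "carriers": co_carriers, "p_value": max(pair_p.values()),
            "pair_p": pair_p, "perfect": perfect,
            "association_ok": compatible or perfect}


def ld_prime(matrix: pd.DataFrame, locus_a: str, locus_b: str,
             coding: str = "dominant") -> tuple[float, float]:
    """Pairwise disequilibrium (D, D') among the lines.

    ``"dominant"`` coding scores each line by donor-carrier presence —
    consistent with the carrier-set logic of the AG analysis; an
    ``"additive"`` option treats the two alleles of each line as
    gametes.  Monomorphic loci make D' undefined (raises).
    """
    sub = matrix[[locus_a, locus_b]].dropna()
    if coding == "dominant":
        xa = (sub[locus_a] >= 1).to_numpy(float)
        xb = (sub[locus_b] >= 1).to_numpy(float)
    elif coding == "additive":
        xa = sub[locus_a].to_numpy(float) / 2.0
        xb = sub[locus_b].to_numpy(float) / 2.0
    else:
        raise ValueError(f"unknown coding {coding!r}")
    pa, pb = xa.mean(), xb.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError(f"monomorphic locus in pair ({locus_a}, {locus_b}): LD undefined")
    d = float((xa * xb).mean() - pa * pb)
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return 0.0, 0.0
    return d, d / dmax


def collapse_linked_loci(matrix: pd.DataFrame,
                         bins: dict[str, str] | None = None) -> pd.DataFrame:
    """Keep one representative marker per linkage bin.

    The representative is the member with the highest call rate (ties
    broken by the lexicographically smallest marker id).  Markers
    without a bin annotation are their own bin; without any annotation
    the matrix passes through unchanged.
    """
    if not bins:
        return matrix
    keep = []
    by_bin: dict[str, list[str]] = {}
    for m in matrix.columns:
        by_bin.setdefault(bins.get(m, f"__solo__{m}"), []).append(m)
    for _, members in sorted(by_bin.items()):
        best = min(members, key=lambda m: (-matrix[m].notna().mean(), m))
        keep.append(best)
    return matrix[[m for m in matrix.columns if m in set(keep)]]


@dataclass(frozen=True)
class FGUCall:
    kind: str  # "single-locus" or "AG"
    loci: tuple[str, ...]
    carriers: frozenset
    carrier_frequency: float
    p_value: float
    perfect: bool = True


def detect_fgus(matrix: pd.DataFrame,
                expectation: IntrogressionExpectation,
                alpha: float = 1e-4,
                bins: dict[str, str] | None = None,
                max_mismatch: int | None = None,
                ag_dprime: float = 0.5) -> list[FGUCall]:
    """Two-stage FGU identification.

    Stage 1: per-locus χ² excess-introgression tests (significant in
    both allelic and genotypic frequencies at ``alpha``).  Stage 2:
    significant loci are clustered into candidate association groups:
    a pair joins when its co-introgression probability passes ``alpha``
    *and* the pair is strongly positively associated (``D' ≥
    ag_dprime``).  The co-introgression probability alone is not an
    association test — with many selected lines it is small even for
    unrelated loci — so the D' gate carries the association evidence;
    set ``ag_dprime = 1.0`` (or ``max_mismatch = 0``) for the strict
    perfect-association behaviour seen in real selected ILs.  Each
    cluster is called an AG; remaining loci are single-locus FGUs.
    """
    matrix = collapse_linked_loci(matrix, bins)
    n = len(matrix)
    sig = []
    for locus in matrix.columns:
        try:
            _, p_allelic = single_locus_excess_test(matrix, locus, expectation, "allelic")
            _, p_geno = single_locus_excess_test(matrix, locus, expectation, "genotypic")
        except ValueError:
            continue
        if p_allelic <= alpha and p_geno <= alpha:
            sig.append(locus)
    sets = carrier_sets(matrix)
    assoc = pd.DataFrame(False, index=sig, columns=sig)
    for a, b in combinations(sig, 2):
        only_a, only_b = len(sets[a] - sets[b]), len(sets[b] - sets[a])
        # strict one-sided containment with a substantial gap is an
        # upstream-downstream inclusion, not same-unit co-membership
        if (only_a == 0) != (only_b == 0) and max(only_a, only_b) >= 0.2 * n:
            continue
        res = ag_probability_test(matrix, [a, b], expectation, max_mismatch)
        try:
            _, dprime = ld_prime(matrix, a, b)
        except ValueError:
            dprime = 1.0  # both carrier sets cover every line: equal, hence associated
        mismatch_ok = res["association_ok"] if max_mismatch is not None else True
        if res["p_value"] <= alpha and dprime >= ag_dprime and mismatch_ok:
            assoc.loc[a, b] = assoc.loc[b, a] = True
    calls: list[FGUCall] = []
    used: set[str] = set()
    graph = nx.Graph()
    graph.add_nodes_from(sig)
    graph.add_edges_from((a, b) for a, b in combinations(sig, 2) if assoc.loc[a, b])
    for comp in sorted(nx.connected_components(graph), key=sorted):
        members = tuple(sorted(comp))
        if len(members) >= 2:
            res = ag_probability_test(matrix, list(members), expectation, max_mismatch)
            calls.append(FGUCall(kind="AG", loci=members, carriers=res["carriers"],
                                 carrier_frequency=res["m"] / n,
                                 p_value=res["p_value"], perfect=res["perfect"]))
            used.update(members)
    sets = carrier_sets(matrix)
    for locus in sig:
        if locus in used:
            continue
        _, p_geno = single_locus_excess_test(matrix, locus, expectation, "genotypic")
        calls.append(FGUCall(kind="single-locus", loci=(locus,),
                             carriers=sets[locus],
                             carrier_frequency=len(sets[locus]) / n,
                             p_value=p_geno))
    return calls


def construct_network(calls: list[FGUCall], matrix: pd.DataFrame,
                      positive_dprime: float = 0.999,
                      negative_dprime: float = -0.5):
    """Hierarchical network from FGU calls and pairwise LD.

    Step 1 groups FGUs that are pairwise positively associated (D' at
    or above the threshold on representative loci, or carrier-set
    inclusion); FGUs in different groups are independent or negative.
    Step 2 layers each group by carrier-set inclusion: an FGU whose
    carriers contain another's sits upstream.  Strong negative
    associations across groups are reported as antagonism edges.
    Output is order-invariant in lines and markers.
    """
    def rep(call: FGUCall) -> str:
        return call.loci[0]

    names = {c: "+".join(c.loci) for c in calls}
    pos = nx.Graph()
    pos.add_nodes_from(names.values())
    neg_edges = []
    for a, b in combinations(calls, 2):
        if a.carriers <= b.carriers or b.carriers <= a.carriers:
            pos.add_edge(names[a], names[b])
            continue
        try:
            _, dp = ld_prime(matrix, rep(a), rep(b))
        except ValueError:
            continue
        if dp >= positive_dprime:
            pos.add_edge(names[a], names[b])
        elif dp <= negative_dprime:
            na, nb = sorted((names[a], names[b]))
            neg_edges.append((na, nb, dp))
    groups = [sorted(comp) for comp in
              sorted(nx.connected_components(pos), key=sorted)]

    g = nx.DiGraph(groups=groups)
    by_name = {names[c]: c for c in calls}
    for name, call in sorted(by_name.items()):
        g.add_node(name, kind=call.kind, loci=call.loci,
                   carrier_frequency=call.carrier_frequency,
                   p_value=call.p_value,
                   group=next(i for i, grp in enumerate(groups) if name in grp))
    for grp in groups:
        for na, nb in combinations(grp, 2):
            ca, cb = by_name[na], by_name[nb]
            if ca.carriers < cb.carriers:
                g.add_edge(nb, na, relation="regulates")
            elif cb.carriers < ca.carriers:
                g.add_edge(na, nb, relation="regulates")
            # equal carrier sets: same layer, no inclusion edge
    for na, nb, dp in neg_edges:
        g.add_edge(na, nb, relation="antagonism", dprime=dp)
    return g
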