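"""Network inference from QTL main- and epistatic-effect tables.

The quantitative-genetics detection arm reads a table of estimated
main effects ``A`` and pairwise epistatic effects ``l`` and applies the
expectation theory in reverse:

* both mains ≈ 0 with strong epistasis  →  a co-adapted multi-locus
  unit (detectable only through its interaction);
* ``A_i ≈ A_j ≈ l``  →  two loci of one unit (type II, mutual
  dependency);
* ``l ≈ c·min(A)`` with clearly unequal mains  →  a regulator chain
  (type I), the larger-effect locus upstream (``c = 1`` in RI/DH,
  ``c = 2/3`` in an F2 under dominance);
* ``l < 0``  →  an antagonistic pattern: the weaker locus expresses in
  the mutant background of the stronger one (repressed branch);
* ``|l| ≈ 0``  →  genetically independent loci.

Classified pairs are assembled into a directed pathway network whose
edges point regulator → regulated; same-unit cliques collapse into
multi-locus units, and pathway effects are re-estimated by inverting
the closed forms given each unit's inferred upstream context.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import networkx as nx

from .population import PopulationType
from .qtl import functional_genotype_frequency

__all__ = [
    "QTLRecord",
    "EpistasisRecord",
    "classify_interaction",
    "build_network",
    "estimate_group_pathway_effects",
]


@dataclass(frozen=True)
class QTLRecord:
    locus: str
    effect: float


@dataclass(frozen=True)
class EpistasisRecord:
    loci: tuple[str, ...]
    effect: float


def _epistasis_factor(population_type: PopulationType) -> float:
    # F2 statements assume complete dominance: l = (2/3) A(downstream)
    return 1.0 if population_type == "RI" else 2.0 / 3.0


def classify_interaction(a_i: float, a_j: float, l_ij: float,
                         population_type: PopulationType = "RI",
                         tolerance: float = 1e-6) -> tuple[str, int | None]:
    """Relationship class of a locus pair from (A_i, A_j, l_ij).

    Returns ``(class, upstream)`` where ``upstream`` is 0 or 1 for a
    type-I (or repressed) orientation and ``None`` otherwise.  Patterns
    matching none of the expectation signatures come back as
    ``"unresolved"`` rather than a silent guess.
    """
    c = _epistasis_factor(population_type)
    tol = tolerance
    if abs(l_ij) <= tol:
        return "independent", None
    if abs(a_i) <= tol and abs(a_j) <= tol:
        return "co-adapted", None
    if l_ij < -tol:
        # expressed in the mutant background of the stronger locus
        up = 0 if abs(a_i) >= abs(a_j) else 1
        return "repressed", up
    lo, hi = sorted((abs(a_i), abs(a_j)))
    if abs(a_i - a_j) <= tol and abs(l_ij - c * a_i) <= tol:
        return "typeII", None
    if abs(l_ij - c * lo) <= tol and hi - lo > tol:
        return "typeI", (0 if abs(a_i) > abs(a_j) else 1)
    return "unresolved", None


def _default_tolerance(mains: dict[str, float]) -> float:
    peak = max((abs(a) for a in mains.values()), default=0.0)
    return 0.05 * peak if peak > 0 else 1e-9


def build_network(qtl_records: list[QTLRecord],
                  epistasis_records: list[EpistasisRecord],
                  population_type: PopulationType = "RI",
                  tolerance: float | None = None) -> nx.DiGraph:
    """Assemble the inferred pathway network.

    Nodes are inferred units (possibly multi-locus) with attributes
    ``members``, ``kind``, ``main_effect``; edges carry ``relation``
    (``regulates`` or ``represses``).  Orientation conflicts leave the
    offending pairs recorded under the graph attribute ``unresolved``.
    The default tolerance is 5% of the largest absolute main effect.
    """
    mains = {r.locus: r.effect for r in qtl_records}
    tol = _default_tolerance(mains) if tolerance is None else tolerance
    pair_class: dict[tuple[str, str], tuple[str, int | None, float]] = {}
    for rec in epistasis_records:
        if len(rec.loci) != 2:
            continue  # higher orders confirm chains but pairs suffice
        i, j = rec.loci
        cls, up = classify_interaction(mains.get(i, 0.0), mains.get(j, 0.0),
                                       rec.effect, population_type, tol)
        pair_class[(i, j)] = (cls, up, rec.effect)

    # group same-unit loci (type II cliques and co-adapted pairs)
    same_unit = nx.Graph()
    same_unit.add_nodes_from(mains)
    co_adapted_loci: set[str] = set()
    for (i, j), (cls, _, _) in pair_class.items():
        same_unit.add_node(i)
        same_unit.add_node(j)
        if cls in ("typeII", "co-adapted"):
            same_unit.add_edge(i, j)
            if cls == "co-adapted":
                co_adapted_loci.update((i, j))
    unit_of: dict[str, str] = {}
    units: dict[str, dict] = {}
    for comp in sorted(nx.connected_components(same_unit), key=sorted):
        members = tuple(sorted(comp))
        uid = "+".join(members)
        kind = "co-adapted" if co_adapted_loci & comp else (
            "multi-locus" if len(members) > 1 else "single-locus")
        within = [eff for (i, j), (cls, _, eff) in pair_class.items()
                  if i in comp and j in comp and cls in ("typeII", "co-adapted")]
        units[uid] = {"members": members, "kind": kind,
                      "main_effect": max((mains.get(m, 0.0) for m in members),
                                         key=abs, default=0.0),
                      "within_epistasis": max(within, key=abs, default=None)}
        for m in members:
            unit_of[m] = uid

    g = nx.DiGraph(unresolved=[])
    for uid, attrs in units.items():
        g.add_node(uid, **attrs)
    for (i, j), (cls, up, eff) in pair_class.items():
        ui, uj = unit_of[i], unit_of[j]
        if ui == uj:
            continue
        if cls in ("typeI", "repressed"):
            src, dst = (ui, uj) if up == 0 else (uj, ui)
            relation = "regulates" if cls == "typeI" else "represses"
            if g.has_edge(dst, src):
                g.graph["unresolved"].append(((i, j), "orientation conflict"))
                continue
            g.add_edge(src, dst, relation=relation, epistasis=eff)
        elif cls == "unresolved":
            g.graph["unresolved"].append(((i, j), "pattern"))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("inferred regulation graph contains a cycle")
    # keep only the direct regulator edges implied by the chain structure
    tr = nx.transitive_reduction(g)
    tr.graph.update(g.graph)
    for n in tr.nodes:
        tr.nodes[n].update(g.nodes[n])
    for u, v in tr.edges:
        tr.edges[u, v].update(g.edges[u, v])
    return tr


def estimate_group_pathway_effects(network: nx.DiGraph,
                                   population_type: PopulationType = "RI",
                                   mode: str = "D") -> dict[str, dict]:
    """Pathway effect ``a`` per inferred unit, from its upstream context.

    For a unit with ``m`` members and ``n`` segregating upstream loci
    (all ancestors in the network), the main effect of one member locus
    satisfies ``A = (a/2)·p^(m−1+n)``; inversion gives ``a``.  A
    co-adapted unit uses ``a = 2·l``.  Units reached only through a
    repressing edge keep a ``direction: decrease``/``undetermined`` tag,
    since the sign of their contribution is not identified without an
    epistatic anchor.
    """
    p = functional_genotype_frequency("S", population_type, mode)
    out: dict[str, dict] = {}
    for node, attrs in network.nodes(data=True):
        members = attrs["members"]
        ancestors = nx.ancestors(network, node)
        n_context = (sum(len(network.nodes[a]["members"]) for a in ancestors)
                     + len(members) - 1)
        if attrs["kind"] == "co-adapted":
            a = 2 * Fraction(attrs["within_epistasis"])
            context = "co-adapted"
        else:
            a = Fraction(attrs["main_effect"]) * 2 / (p ** n_context)
            context = "ok"
        in_relations = {network.edges[pred, node]["relation"]
                        for pred in network.predecessors(node)}
        anchored = (attrs["kind"] != "single-locus"
                    or network.in_degree(node) > 0 or network.out_degree(node) > 0)
        if in_relations == {"represses"}:
            direction = "decrease"
        elif anchored:
            direction = "increase"
        else:
            direction = "undetermined"
        out[node] = {"pathway_effect": float(a), "direction": direction,
                     "context": context}
    return out
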