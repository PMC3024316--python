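"""Shared I/O: genotype matrices, effect tables, population tables, networks.

All tabular formats are UTF-8, tab-delimited text with header rows;
trait values are printed at 6 significant digits.  Networks serialize
losslessly to JSON and with node/edge attributes to GraphML and DOT.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .population import PopulationTable
from .qtl_network import EpistasisRecord, QTLRecord

__all__ = [
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_effect_table",
    "write_effect_table",
    "write_population_table",
    "write_network",
    "network_to_dict",
]

_DEFAULT_CODES = {"0": 0, "1": 1, "2": 2, "NA": None}


def read_genotype_matrix(path: str | Path,
                         codes: dict[str, int | None] | None = None) -> pd.DataFrame:
    """Read a lines × markers matrix of genotype codes.

    Unknown codes are a hard error naming every offending cell.
    Missing values come back as NaN; the frame carries a
    ``missing_rate`` attribute.
    """
    codes = _DEFAULT_CODES if codes is None else codes
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    bad = []
    for marker in raw.columns:
        for line, cell in raw[marker].items():
            if str(cell) not in codes:
                bad.append((line, marker, cell))
    if bad:
        listing = "; ".join(f"line {l!r} marker {m!r}: {c!r}" for l, m, c in bad[:20])
        raise ValueError(f"{len(bad)} cells with unknown genotype codes: {listing}")
    out = raw.apply(lambda col: col.map(lambda c: codes[str(c)])).astype(float)
    out.attrs["missing_rate"] = float(out.isna().mean().mean())
    return out


def write_genotype_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    enc = matrix.copy()
    enc = enc.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    enc.to_csv(path, sep="\t")


def write_population_table(table: PopulationTable, path: str | Path) -> None:
    """Genotype code string, frequency and trait value per class."""
    rows = [{"genotype": "".join(map(str, c.states)),
             "frequency": f"{float(c.frequency):.10g}",
             "value": f"{float(c.value):.6g}"} for c in table.classes]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_effect_table(path: str | Path) -> tuple[list[QTLRecord], list[EpistasisRecord]]:
    """Delimited effect table: columns ``term`` (main/epistasis), ``loci``
    (comma-separated ids) and ``effect``."""
    frame = pd.read_csv(path, sep="\t", dtype={"term": str, "loci": str})
    mains, epis = [], []
    for _, row in frame.iterrows():
        loci = tuple(str(row["loci"]).split(","))
        if row["term"] == "main":
            mains.append(QTLRecord(locus=loci[0], effect=float(row["effect"])))
        elif row["term"] == "epistasis":
            epis.append(EpistasisRecord(loci=loci, effect=float(row["effect"])))
        else:
            raise ValueError(f"unknown term type {row['term']!r}")
    return mains, epis


def write_effect_table(mains: list[QTLRecord], epis: list[EpistasisRecord],
                       path: str | Path,
                       shares: dict[tuple[str, ...], float] | None = None) -> None:
    rows = []
    for r in mains:
        rows.append({"term": "main", "loci": r.locus,
                     "effect": f"{r.effect:.6g}",
                     "variance_share": f"{shares.get((r.locus,), float('nan')):.6g}"
                     if shares else ""})
    for r in epis:
        rows.append({"term": "epistasis", "loci": ",".join(r.loci),
                     "effect": f"{r.effect:.6g}",
                     "variance_share": f"{shares.get(tuple(r.loci), float('nan')):.6g}"
                     if shares else ""})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _jsonable(value):
    if isinstance(value, (frozenset, set)):
        return sorted(value)
    if isinstance(value, tuple):
        return list(value)
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def network_to_dict(network: nx.DiGraph) -> dict:
    return {
        "graph": {k: _jsonable(v) for k, v in network.graph.items()},
        "nodes": [{"id": n, **{k: _jsonable(v) for k, v in d.items()}}
                  for n, d in network.nodes(data=True)],
        "edges": [{"source": u, "target": v,
                   **{k: _jsonable(w) for k, w in d.items()}}
                  for u, v, d in network.edges(data=True)],
    }


def write_network(network: nx.DiGraph, path: str | Path, fmt: str = "json") -> None:
    """Serialize a pathway network: lossless JSON, or GraphML/DOT with
    node/edge attributes (DOT clusters nodes by branch/group)."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(network_to_dict(network), indent=2))
        return
    if fmt == "graphml":
        g = network.copy()
        g.graph.pop("groups", None)
        g.graph.pop("unresolved", None)
        for _, d in g.nodes(data=True):
            for k, v in list(d.items()):
                if v is None:
                    del d[k]
                elif isinstance(v, (tuple, frozenset, set, list)):
                    d[k] = ",".join(map(str, sorted(v) if isinstance(v, (set, frozenset)) else v))
        nx.write_graphml(g, path)
        return
    if fmt == "dot":
        lines = ["digraph pathway {"]
        groups = network.graph.get("groups")
        if groups:
            for i, grp in enumerate(groups):
                lines.append(f"  subgraph cluster_{i} {{")
                lines.append(f'    label="group {i}";')
                for n in grp:
                    lines.append(f'    "{n}";')
                lines.append("  }")
        for n, d in network.nodes(data=True):
            label = d.get("kind", "")
            lines.append(f'  "{n}" [label="{n}\\n{label}"];')
        for u, v, d in network.edges(data=True):
            style = {"represses": "tee", "antagonism": "odot"}.get(
                d.get("relation"), "normal")
            lines.append(f'  "{u}" -> "{v}" [arrowhead={style}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
        return
    raise ValueError(f"unknown network format {fmt!r}")
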