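"""BioGRID tab-format parsing and seed-gene subnetwork extraction.

The interactome is an undirected simple graph on official gene symbols:
multiple evidence lines for one interactor pair collapse to a single
edge, self-interactions are dropped, and both removals are counted in a
parse report.  Given a seed gene set (here: the genes of the consistent
decoupling pairs), :func:`direct_neighborhood` extracts the subgraph of
the seeds and their direct interaction partners and reports the
direct-interaction and partner counts.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ParseReport",
    "NeighborhoodResult",
    "parse_biogrid_tab",
    "direct_neighborhood",
    "export_graph",
    "import_graphml",
    "degree_report",
]


@dataclasses.dataclass
class ParseReport:
    """Bookkeeping from one BioGRID tab parse."""

    n_interaction_lines: int = 0
    n_duplicate_edges: int = 0
    n_self_loops: int = 0
    n_skipped_rows: int = 0


@dataclasses.dataclass
class NeighborhoodResult:
    """Direct-interaction subnetwork of a seed gene set."""

    subgraph: nx.Graph
    seed_degrees: dict[str, int]
    n_direct_interactions: int
    n_partners: int
    n_partners_in_reference_list: int | None


def _find_header(lines: list[str]) -> tuple[int, list[str]]:
    for i, line in enumerate(lines):
        if "INTERACTOR_A" in line.upper():
            return i, line.lstrip("#").rstrip("\n").split("\t")
    raise ValueError("malformed BioGRID tab file: no INTERACTOR_A header line found")


def _symbol_columns(header: list[str]) -> tuple[int, int]:
    upper = [h.strip().upper() for h in header]
    sym_a = sym_b = None
    for i, name in enumerate(upper):
        if "OFFICIAL_SYMBOL" in name:
            if name.endswith("A") and sym_a is None:
                sym_a = i
            elif name.endswith("B") and sym_b is None:
                sym_b = i
    if sym_a is None or sym_b is None:
        raise ValueError(
            "malformed BioGRID tab header: OFFICIAL_SYMBOL columns for both "
            "interactors are required"
        )
    return sym_a, sym_b


def _organism_columns(header: list[str]) -> tuple[int | None, int | None]:
    upper = [h.strip().upper() for h in header]
    org_a = org_b = None
    for i, name in enumerate(upper):
        if "ORGANISM" in name:
            if name.endswith("A_ID") or name.endswith("A"):
                org_a = i
            elif name.endswith("B_ID") or name.endswith("B"):
                org_b = i
    return org_a, org_b


def parse_biogrid_tab(
    path: str | Path,
    organism_filter: int | str | None = None,
    experimental_system: str | None = None,
) -> tuple[nx.Graph, ParseReport]:
    """Parse a BioGRID tab-format interaction file into a simple graph.

    Node identity is the official gene symbol.  Rows with an empty or
    placeholder ("-", "N/A") symbol are skipped and counted; evidence
    lines repeating a pair (in either orientation) collapse to one edge;
    self-interactions are dropped.  ``organism_filter`` (an NCBI taxon
    id) keeps only rows where both interactors match, when organism
    columns are present; ``experimental_system`` filters on the
    EXPERIMENTAL_SYSTEM column when present.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8", errors="replace")
    if not text.strip():
        raise ValueError(f"empty BioGRID file: {path}")
    lines = text.splitlines()
    header_idx, header = _find_header(lines)
    sym_a, sym_b = _symbol_columns(header)
    org_a, org_b = _organism_columns(header)
    try:
        sys_col: int | None = [h.strip().upper() for h in header].index(
            "EXPERIMENTAL_SYSTEM"
        )
    except ValueError:
        sys_col = None

    graph = nx.Graph()
    report = ParseReport()
    bad_symbols = {"", "-", "N/A", "NA"}
    for raw in lines[header_idx + 1:]:
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) <= max(sym_a, sym_b):
            report.n_skipped_rows += 1
            continue
        report.n_interaction_lines += 1
        a = fields[sym_a].strip()
        b = fields[sym_b].strip()
        if a in bad_symbols or b in bad_symbols:
            report.n_skipped_rows += 1
            continue
        if organism_filter is not None and org_a is not None and org_b is not None:
            want = str(organism_filter)
            if fields[org_a].strip() != want or fields[org_b].strip() != want:
                report.n_skipped_rows += 1
                continue
        if experimental_system is not None and sys_col is not None:
            if len(fields) <= sys_col or fields[sys_col].strip() != experimental_system:
                report.n_skipped_rows += 1
                continue
        if a == b:
            report.n_self_loops += 1
            continue
        if graph.has_edge(a, b):
            report.n_duplicate_edges += 1
            continue
        graph.add_edge(a, b)
    if graph.number_of_edges() == 0:
        warnings.warn(f"BioGRID file {path} yielded no interactions", stacklevel=2)
    return graph, report


def direct_neighborhood(
    g: nx.Graph,
    seeds: Sequence[str],
    reference_list: Iterable[str] | None = None,
) -> NeighborhoodResult:
    """Subnetwork of seed genes and their direct interaction partners.

    The subgraph keeps exactly the edges incident to at least one seed
    (seed-seed edges count once).  ``n_partners_in_reference_list``
    counts distinct non-seed partners present in ``reference_list``
    (e.g. the glucose-metabolism panel); None when no list is supplied.
    """
    if not seeds:
        raise ValueError("seed set is empty")
    seed_set = set(seeds)
    present = seed_set & set(g.nodes)
    if not present:
        raise ValueError("none of the seed genes are present in the interaction graph")

    sub = nx.Graph()
    sub.add_nodes_from(present)
    for s in sorted(present):
        for nb in g.neighbors(s):
            sub.add_edge(s, nb)
    for node in sub.nodes:
        sub.nodes[node]["is_seed"] = node in seed_set
    sub.graph["seed_set"] = sorted(present)

    partners = set(sub.nodes) - seed_set
    n_ref = None
    if reference_list is not None:
        n_ref = len(partners & set(reference_list))
    return NeighborhoodResult(
        subgraph=sub,
        seed_degrees={s: sub.degree(s) for s in sorted(present)},
        n_direct_interactions=sub.number_of_edges(),
        n_partners=len(partners),
        n_partners_in_reference_list=n_ref,
    )


def export_graph(g: nx.Graph, format: str, out: str | Path) -> None:
    """Write a graph as Cytoscape-readable SIF or as GraphML.

    SIF: one ``A pp B`` line per edge (plus bare lines for isolated
    nodes).  GraphML: full round-trip including the boolean ``is_seed``
    node attribute.
    """
    out = Path(out)
    if format == "sif":
        with open(out, "w", encoding="utf-8") as fh:
            for a, b in sorted(map(sorted, g.edges())):
                fh.write(f"{a} pp {b}\n")
            for node in sorted(nx.isolates(g)):
                fh.write(f"{node}\n")
    elif format == "graphml":
        h = nx.Graph()
        h.add_nodes_from(sorted(g.nodes(data=True)))
        h.add_edges_from(sorted(map(tuple, map(sorted, g.edges()))))
        nx.write_graphml(h, out)
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_graphml(path: str | Path) -> nx.Graph:
    """Read a GraphML export back; inverse of ``export_graph(..., "graphml")``."""
    return nx.read_graphml(Path(path))


def degree_report(result: NeighborhoodResult) -> pd.DataFrame:
    """Per-node degrees in the neighborhood subgraph (symbol, is_seed, degree)."""
    rows = [
        {
            "symbol": node,
            "is_seed": bool(result.subgraph.nodes[node].get("is_seed", False)),
            "degree": result.subgraph.degree(node),
        }
        for node in result.subgraph.nodes
    ]
    return (
        pd.DataFrame(rows, columns=["symbol", "is_seed", "degree"])
        .sort_values(["degree", "symbol"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
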