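"""Weighted quote co-occurrence ("co-sort") networks.

Nodes are quotes; an edge joins two quotes if at least one researcher placed
them in the same pile, and the integer edge weight counts how many
researchers did so.  Quotes that were never co-placed with anything are kept
as isolated nodes so that every quote appears in the grouped output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

import networkx as nx

from .sortdata import (
    PilesortError,
    QuoteId,
    SortingStudy,
    format_quote_id,
    parse_quote_id,
)

EXPORT_FORMATS = ("graphml", "gml", "dot", "edgelist")


@dataclass
class CoSortNetwork:
    """Symmetric weighted graph over quote ids.

    ``graph`` is an undirected :class:`networkx.Graph` whose nodes are
    integer quote ids and whose edges carry an integer ``weight`` attribute
    (the number of co-placing researchers).  ``n_researchers`` bounds every
    weight from above.
    """

    graph: nx.Graph
    n_researchers: int = field(default=0)

    @property
    def nodes(self) -> list[QuoteId]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, i: QuoteId, j: QuoteId) -> int:
        """Co-placement count for the unordered pair {i, j} (0 if no edge)."""
        if i == j:
            return 0
        data = self.graph.get_edge_data(i, j)
        return 0 if data is None else int(data["weight"])

    def total_weight(self) -> int:
        """Sum of weights over unordered pairs (the handshake total)."""
        return sum(int(d["weight"]) for _, _, d in self.graph.edges(data=True))


def build_cosort_network(study: SortingStudy) -> CoSortNetwork:
    """Accumulate per-researcher co-placements into the weighted network.

    For every unordered quote pair {i, j} the weight is the number of
    researchers whose partition puts i and j in the same pile.  All study
    quotes become nodes, co-placed or not.
    """
    g = nx.Graph()
    g.add_nodes_from(study.quotes)
    for researcher in study.researchers:
        for pile_quotes in study.piles_of(researcher).values():
            for i, j in combinations(pile_quotes, 2):
                if g.has_edge(i, j):
                    g[i][j]["weight"] += 1
                else:
                    g.add_edge(i, j, weight=1)
    return CoSortNetwork(graph=g, n_researchers=study.n_researchers)


def _canonical_graph(
    net: CoSortNetwork, assignment: Mapping[QuoteId, object] | None
) -> nx.Graph:
    """Relabel nodes to canonical ID strings and attach group attributes."""
    g = nx.Graph(n_researchers=int(net.n_researchers))
    for q in net.nodes:
        attrs = {}
        if assignment is not None:
            if q not in assignment:
                raise PilesortError(
                    f"assignment does not cover node {format_quote_id(q)}"
                )
            attrs["group"] = str(assignment[q])
        g.add_node(format_quote_id(q), **attrs)
    for i, j, d in net.graph.edges(data=True):
        g.add_edge(format_quote_id(i), format_quote_id(j), weight=int(d["weight"]))
    return g


def export_network(
    net: CoSortNetwork,
    path: str | Path,
    format: str = "graphml",
    assignment: Mapping[QuoteId, object] | None = None,
) -> Path:
    """Write the network to ``path`` in one of the supported formats.

    Nodes are written with canonical quote ids; edges carry an integer
    ``weight`` attribute; when an ``assignment`` is given every node gets a
    string ``group`` attribute.  ``graphml``, ``gml`` and ``edgelist``
    round-trip exactly through :func:`import_network`; ``dot`` is written in
    a plain subset of the Graphviz language that this module can also read
    back.
    """
    if format not in EXPORT_FORMATS:
        raise PilesortError(
            f"unknown format {format!r}; choose one of {', '.join(EXPORT_FORMATS)}"
        )
    path = Path(path)
    g = _canonical_graph(net, assignment)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "gml":
        nx.write_gml(g, path)
    elif format == "edgelist":
        lines = [f"# n_researchers={net.n_researchers}"]
        for q in g.nodes:
            if g.degree(q) == 0:
                lines.append(f"{q}")
        for i, j, d in g.edges(data=True):
            lines.append(f"{i} {j} {d['weight']}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "dot":
        path.write_text(_to_dot(g, net.n_researchers), encoding="utf-8")
    return path


def _to_dot(g: nx.Graph, n_researchers: int) -> str:
    lines = ["graph cosort {", f'  graph [n_researchers="{n_researchers}"];']
    for node, attrs in g.nodes(data=True):
        if "group" in attrs:
            lines.append(f'  "{node}" [group="{attrs["group"]}"];')
        else:
            lines.append(f'  "{node}";')
    max_w = max((d["weight"] for _, _, d in g.edges(data=True)), default=1)
    for i, j, d in g.edges(data=True):
        w = d["weight"]
        lines.append(f'  "{i}" -- "{j}" [weight="{w}", penwidth="{1 + 4 * w / max_w:.2f}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def _from_dot(text: str) -> nx.Graph:
    # parses only the subset emitted by _to_dot
    import re

    g = nx.Graph()
    node_re = re.compile(r'^\s*"([^"]+)"\s*(?:\[group="([^"]*)"\])?\s*;')
    edge_re = re.compile(r'^\s*"([^"]+)"\s*--\s*"([^"]+)"\s*\[weight="(\d+)"')
    graph_re = re.compile(r'n_researchers="(\d+)"')
    for ln in text.splitlines():
        m = graph_re.search(ln)
        if m and "graph [" in ln:
            g.graph["n_researchers"] = int(m.group(1))
        m = edge_re.match(ln)
        if m:
            g.add_edge(m.group(1), m.group(2), weight=int(m.group(3)))
            continue
        m = node_re.match(ln)
        if m:
            g.add_node(m.group(1))
            if m.group(2) is not None:
                g.nodes[m.group(1)]["group"] = m.group(2)
    return g


def import_network(path: str | Path, format: str | None = None) -> CoSortNetwork:
    """Read a network previously written by :func:`export_network`."""
    path = Path(path)
    if format is None:
        format = {".graphml": "graphml", ".gml": "gml", ".dot": "dot"}.get(
            path.suffix, "edgelist"
        )
    if format not in EXPORT_FORMATS:
        raise PilesortError(f"unknown format {format!r}")
    if format == "graphml":
        g = nx.read_graphml(path)
    elif format == "gml":
        g = nx.read_gml(path)
    elif format == "dot":
        g = _from_dot(path.read_text(encoding="utf-8"))
    else:
        g = nx.Graph()
        for ln in path.read_text(encoding="utf-8").splitlines():
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                if "n_researchers=" in ln:
                    g.graph["n_researchers"] = int(ln.split("=", 1)[1])
                continue
            parts = ln.split()
            if len(parts) == 1:
                g.add_node(parts[0])
            else:
                g.add_edge(parts[0], parts[1], weight=int(parts[2]))
    out = nx.Graph()
    for node in g.nodes:
        out.add_node(parse_quote_id(node))
    for i, j, d in g.edges(data=True):
        out.add_edge(parse_quote_id(i), parse_quote_id(j), weight=int(d["weight"]))
    n_r = int(g.graph.get("n_researchers", 0))
    return CoSortNetwork(graph=out, n_researchers=n_r)


def spring_layout(net: CoSortNetwork, seed: int = 0) -> dict[QuoteId, tuple[float, float]]:
    """Deterministic force-directed placement (proximity tracks similarity)."""
    pos = nx.spring_layout(net.graph, weight="weight", seed=seed)
    return {q: (float(x), float(y)) for q, (x, y) in pos.items()}
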