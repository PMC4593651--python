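"""Graph and attribute-table input/output.

Networks are plain :class:`networkx.Graph` / :class:`networkx.DiGraph`
objects with **string** vertex identifiers and no self-loops or parallel
edges.  All iteration the package performs is in lexicographic vertex
order so that every output is reproducible regardless of insertion order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "AttributeMap",
    "read_edge_list",
    "write_edge_list",
    "read_graphml",
    "write_graphml",
    "read_attribute_table",
    "to_undirected",
    "largest_component",
]


@dataclass(frozen=True)
class AttributeMap:
    """Assignment of each vertex to one of ``K`` groups coded ``1..K``.

    Parameters
    ----------
    codes
        Mapping vertex -> integer group code in ``1..K``.
    labels
        Group names; ``labels[g - 1]`` is the name of group ``g``.
    """

    codes: Mapping[str, int]
    labels: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bad = {c for c in self.codes.values() if not isinstance(c, int) or c < 1}
        if bad:
            raise ValueError(f"group codes must be integers >= 1, got {sorted(map(str, bad))}")
        if self.labels and max(self.codes.values(), default=0) > len(self.labels):
            raise ValueError("a group code exceeds the number of group labels")

    @property
    def n_groups(self) -> int:
        """K: the number of groups (labelled groups may be uninhabited)."""
        return max(len(self.labels), max(self.codes.values(), default=0))

    def __getitem__(self, vertex: str) -> int:
        return self.codes[vertex]

    def group_label(self, g: int) -> str:
        if self.labels:
            return self.labels[g - 1]
        return str(g)

    def members(self, g: int) -> list[str]:
        return sorted(v for v, c in self.codes.items() if c == g)

    def validate(self, net: nx.Graph) -> None:
        """Raise ``KeyError`` naming any vertex of ``net`` without a code."""
        missing = sorted(v for v in net.nodes if v not in self.codes)
        if missing:
            raise KeyError(f"vertices without an attribute: {missing}")

    def restrict(self, vertices: Iterable[str]) -> "AttributeMap":
        """Attribute map restricted to ``vertices`` (codes unchanged)."""
        keep = set(vertices)
        return AttributeMap({v: c for v, c in self.codes.items() if v in keep}, self.labels)


def _new_graph(directed: bool) -> nx.Graph:
    return nx.DiGraph() if directed else nx.Graph()


def read_edge_list(path: str | Path, directed: bool = False) -> nx.Graph:
    """Read a whitespace/TSV two-column edge list into a simple graph.

    Lines starting with ``#`` are comments.  Duplicate rows are collapsed
    and self-loop rows dropped (both logged).  Raises ``ValueError`` on a
    row with fewer than two columns, naming the line number, and on an
    empty file.
    """
    net = _new_graph(directed)
    n_loops = 0
    n_dups = 0
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected >=2 columns, got {len(parts)}")
            u, v = parts[0], parts[1]
            n_rows += 1
            if u == v:
                n_loops += 1
                continue
            if net.has_edge(u, v):
                n_dups += 1
                continue
            net.add_edge(u, v)
    if n_rows == 0:
        raise ValueError(f"{path}: empty edge list")
    if n_loops:
        logger.info("%s: dropped %d self-loop row(s)", path, n_loops)
    if n_dups:
        logger.info("%s: collapsed %d duplicate row(s)", path, n_dups)
    return net


def write_edge_list(net: nx.Graph, path: str | Path, header: str | None = None) -> None:
    """Write a two-column TSV edge list in lexicographic edge order."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        if net.is_directed():
            edges = sorted(net.edges())
        else:
            edges = sorted(tuple(sorted(e)) for e in net.edges())
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_graphml(path: str | Path) -> nx.Graph:
    """Read a GraphML file, normalizing to a simple graph with string ids."""
    g = nx.read_graphml(path)
    net = _new_graph(g.is_directed())
    net.add_nodes_from(str(v) for v in g.nodes)
    for u, v in g.edges():
        u, v = str(u), str(v)
        if u != v:
            net.add_edge(u, v)
    return net


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, path)


def read_attribute_table(
    path: str | Path,
    net: nx.Graph | None = None,
    label_order: Sequence[str] | None = None,
) -> AttributeMap:
    """Read a TSV of ``vertex<TAB>group_label`` rows into an AttributeMap.

    Labels are mapped to codes ``1..K`` in first-appearance order unless
    ``label_order`` pins the coding explicitly.  When ``net`` is given,
    vertices of the network missing from the table raise ``KeyError``;
    table vertices unknown to the network are kept with a warning.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            rows.append((parts[0], parts[1]))
    labels: list[str] = list(label_order) if label_order else []
    codes: dict[str, int] = {}
    for vertex, label in rows:
        if label not in labels:
            if label_order is not None:
                raise ValueError(f"label {label!r} not in supplied label order")
            labels.append(label)
        codes[vertex] = labels.index(label) + 1
    attrs = AttributeMap(codes, tuple(labels))
    if net is not None:
        attrs.validate(net)
        unknown = sorted(v for v in codes if v not in net.nodes)
        if unknown:
            logger.warning("%s: %d attributed vertex(es) not in network: %s",
                           path, len(unknown), unknown[:10])
    return attrs


def to_undirected(net: nx.Graph) -> nx.Graph:
    """Symmetrize a digraph: ``{u, v}`` present iff ``u->v`` or ``v->u``.

    Passing an already-undirected graph returns a copy with a warning.
    """
    if not net.is_directed():
        logger.warning("to_undirected: input already undirected; returning a copy")
        return net.copy()
    und = nx.Graph()
    und.add_nodes_from(net.nodes)
    und.add_edges_from(net.edges())
    return und


def largest_component(net: nx.Graph, mode: str = "connected") -> nx.Graph:
    """Induced subgraph on the largest component.

    ``mode`` is ``"strong"`` or ``"weak"`` for digraphs, ``"connected"``
    for undirected graphs.  Ties are broken by the lexicographically
    smallest member vertex.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network has no components")
    if net.is_directed():
        if mode == "strong":
            comps = nx.strongly_connected_components(net)
        elif mode == "weak":
            comps = nx.weakly_connected_components(net)
        else:
            raise ValueError(f"mode {mode!r} invalid for a directed network")
    else:
        if mode != "connected":
            raise ValueError(f"mode {mode!r} invalid for an undirected network")
        comps = nx.connected_components(net)
    comp_list = list(comps)
    max_size = max(len(c) for c in comp_list)
    best = min((c for c in comp_list if len(c) == max_size), key=min)
    return net.subgraph(best).copy()
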