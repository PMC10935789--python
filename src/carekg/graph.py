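"""In-memory labelled directed property graph with schema validation.

Nodes are identified by (label, canonical name); the canonical form is
case-folded and whitespace-collapsed so questionnaire entries and curated
knowledge rows merge onto shared concept nodes.  Edges are stored directed but
pattern matching and path search treat them as undirected by default, matching
how care knowledge is queried in practice (a drug "treats" a disease answers
both "what treats X" and "what does Y treat").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, NamedTuple

import networkx as nx

from .errors import NotFoundError, SchemaViolationError
from .schema import SchemaConstraint, default_schema

Scalar = str | int | float | bool

_WS = re.compile(r"\s+")


def canonical_name(name: str) -> str:
    """Case-folded, whitespace-trimmed/collapsed node identity key."""
    return _WS.sub(" ", name.strip()).casefold()


def node_id(label: str, name: str) -> str:
    return f"{label}:{canonical_name(name)}"


@dataclass
class Node:
    id: str
    label: str
    name: str  # display form as first seen
    attributes: dict[str, Scalar] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return canonical_name(self.name)


@dataclass
class Edge:
    source: str  # node id
    target: str  # node id
    category: str
    attributes: dict[str, Scalar] = field(default_factory=dict)

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.category)


class Violation(NamedTuple):
    element: str  # node id or "source->target[category]"
    rule: str     # short rule identifier
    message: str


@dataclass
class Path:
    """A simple path: node ids plus the traversed edges (evidence)."""

    nodes: list[str]
    edges: list[Edge]

    def __len__(self) -> int:
        return len(self.edges)


class KnowledgeGraph:
    """Schema-constrained directed property graph.

    Parameters
    ----------
    schema:
        Concept-layer constraints; defaults to the packaged 31-label /
        9-category layer.
    """

    def __init__(self, schema: SchemaConstraint | None = None):
        self.schema = schema or default_schema()
        self._g = nx.MultiDiGraph()
        #: raw sensor history per elder (canonical name) — kept out of the graph
        self.reading_logs: dict[str, list[dict[str, Any]]] = {}

    # ------------------------------------------------------------------ nodes

    def add_node(
        self,
        label: str,
        name: str,
        attributes: dict[str, Scalar] | None = None,
    ) -> str:
        """Upsert a node; returns its id.

        Re-adding an existing (label, name) merges the attribute map into the
        stored node and returns the same id.
        """
        if not self.schema.allows_label(label):
            raise SchemaViolationError(f"unknown node label {label!r}")
        attributes = dict(attributes or {})
        allowed = self.schema.allowed_attributes(label)
        for key in attributes:
            if key not in allowed:
                raise SchemaViolationError(
                    f"attribute {key!r} not permitted on label {label!r}"
                )
        nid = node_id(label, name)
        if nid in self._g:
            self._g.nodes[nid]["node"].attributes.update(attributes)
        else:
            self._g.add_node(nid, node=Node(nid, label, name.strip(), attributes))
        return nid

    def get_node(self, nid: str) -> Node:
        try:
            return self._g.nodes[nid]["node"]
        except KeyError:
            raise NotFoundError(f"no node with id {nid!r}") from None

    def find_node(self, label: str, name: str) -> Node | None:
        nid = node_id(label, name)
        if nid in self._g:
            return self._g.nodes[nid]["node"]
        return None

    def has_node(self, nid: str) -> bool:
        return nid in self._g

    def nodes(self, label: str | None = None) -> list[Node]:
        out = [d["node"] for _, d in self._g.nodes(data=True)]
        if label is not None:
            out = [n for n in out if n.label == label]
        return sorted(out, key=lambda n: (n.label, n.key))

    @property
    def node_count(self) -> int:
        return self._g.number_of_nodes()

    # ------------------------------------------------------------------ edges

    def add_edge(
        self,
        source: str,
        target: str,
        category: str,
        attributes: dict[str, Scalar] | None = None,
    ) -> Edge:
        """Insert a directed edge; duplicate (source, target, category) is a
        no-op that returns the stored edge."""
        for nid in (source, target):
            if nid not in self._g:
                raise NotFoundError(f"edge endpoint {nid!r} does not exist")
        src, tgt = self.get_node(source), self.get_node(target)
        if not self.schema.allows_category(category):
            raise SchemaViolationError(f"unknown relation category {category!r}")
        if not self.schema.allows_edge(src.label, tgt.label, category):
            raise SchemaViolationError(
                f"pattern ({src.label}, {tgt.label}, {category}) not permitted"
            )
        if self._g.has_edge(source, target, key=category):
            return self._g[source][target][category]["edge"]
        edge = Edge(source, target, category, dict(attributes or {}))
        self._g.add_edge(source, target, key=category, edge=edge)
        return edge

    def remove_edge(self, source: str, target: str, category: str) -> None:
        if not self._g.has_edge(source, target, key=category):
            raise NotFoundError(f"no edge {source}->{target}[{category}]")
        self._g.remove_edge(source, target, key=category)

    def has_edge(self, source: str, target: str, category: str) -> bool:
        return self._g.has_edge(source, target, key=category)

    def edges(self) -> list[Edge]:
        out = [d["edge"] for _, _, d in self._g.edges(data=True)]
        return sorted(out, key=lambda e: (e.source, e.category, e.target))

    @property
    def edge_count(self) -> int:
        return self._g.number_of_edges()

    def edges_touching(self, nid: str) -> list[Edge]:
        """All edges incident to a node, either direction, sorted."""
        if nid not in self._g:
            raise NotFoundError(f"no node with id {nid!r}")
        out = [d["edge"] for _, _, d in self._g.out_edges(nid, data=True)]
        out += [d["edge"] for _, _, d in self._g.in_edges(nid, data=True)]
        return sorted(out, key=lambda e: (e.source, e.category, e.target))

    def _force_edge(self, edge: Edge) -> None:
        # test hook: bypass schema checks to inject a fault
        self._g.add_edge(edge.source, edge.target, key=edge.category, edge=edge)

    # ------------------------------------------------------------- validation

    def validate_schema(self) -> list[Violation]:
        """Report (never raise) every node/edge breaking the concept layer."""
        out: list[Violation] = []
        for node in self.nodes():
            if not self.schema.allows_label(node.label):
                out.append(Violation(node.id, "unknown-label",
                                     f"label {node.label!r} outside the schema"))
                continue
            allowed = self.schema.allowed_attributes(node.label)
            for key in sorted(node.attributes):
                if key not in allowed:
                    out.append(Violation(node.id, "disallowed-attribute",
                                         f"attribute {key!r} not permitted on "
                                         f"{node.label!r}"))
        for edge in self.edges():
            ident = f"{edge.source}->{edge.target}[{edge.category}]"
            if edge.source not in self._g or edge.target not in self._g:
                out.append(Violation(ident, "dangling-endpoint",
                                     "edge endpoint missing"))
                continue
            src, tgt = self.get_node(edge.source), self.get_node(edge.target)
            if not self.schema.allows_category(edge.category):
                out.append(Violation(ident, "unknown-category",
                                     f"category {edge.category!r} outside the schema"))
            elif not self.schema.allows_edge(src.label, tgt.label, edge.category):
                out.append(Violation(ident, "disallowed-pattern",
                                     f"({src.label}, {tgt.label}, {edge.category}) "
                                     "not in edge_patterns"))
        return out

    # ------------------------------------------------------------ path search

    def _adjacent(self, nid: str, direction: str) -> Iterator[tuple[str, Edge]]:
        for _, nbr, d in self._g.out_edges(nid, data=True):
            yield nbr, d["edge"]
        if direction == "undirected":
            for nbr, _, d in self._g.in_edges(nid, data=True):
                yield nbr, d["edge"]

    def find_paths(
        self,
        start: str,
        end_label: str,
        max_depth: int,
        direction: str = "undirected",
    ) -> list[Path]:
        """All simple paths from ``start`` to any node of ``end_label`` of
        length <= ``max_depth`` (1..4), in deterministic lexicographic order
        of the node names along the path.

        This is the bounded "two-step, three-step" neighbourhood search used
        for care-risk discovery; parallel edges between the same node pair
        yield distinct paths.
        """
        if start not in self._g:
            raise NotFoundError(f"no node with id {start!r}")
        if not 1 <= max_depth <= 4:
            raise ValueError("max_depth must be between 1 and 4")
        if direction not in ("directed", "undirected"):
            raise ValueError("direction must be 'directed' or 'undirected'")

        results: list[Path] = []

        def dfs(current: str, nodes: list[str], edges: list[Edge]) -> None:
            if edges and self.get_node(current).label == end_label:
                results.append(Path(list(nodes), list(edges)))
            if len(edges) >= max_depth:
                return
            for nbr, edge in self._adjacent(current, direction):
                if nbr in nodes:
                    continue  # simple paths only
                nodes.append(nbr)
                edges.append(edge)
                dfs(nbr, nodes, edges)
                nodes.pop()
                edges.pop()

        dfs(start, [start], [])
        results.sort(key=lambda p: ([self.get_node(n).key for n in p.nodes],
                                    [e.category for e in p.edges]))
        return results

    # --------------------------------------------------------------- matching

    def match_triples(
        self,
        source_label: str | None = None,
        category: str | None = None,
        target_label: str | None = None,
        source_name: str | None = None,
    ) -> list[tuple[Node, Edge, Node]]:
        """Every edge matching the (label, category, label) pattern, edge
        direction ignored; ``None`` is a wildcard.

        Results are oriented so the node playing the source role comes first,
        and ordered deterministically.
        """
        want_name = canonical_name(source_name) if source_name is not None else None

        def role_match(a: Node, b: Node) -> bool:
            if source_label is not None and a.label != source_label:
                return False
            if target_label is not None and b.label != target_label:
                return False
            if want_name is not None and a.key != want_name:
                return False
            return True

        out: list[tuple[Node, Edge, Node]] = []
        seen: set[tuple[str, str, str]] = set()
        for edge in self.edges():
            if category is not None and edge.category != category:
                continue
            u, v = self.get_node(edge.source), self.get_node(edge.target)
            for a, b in ((u, v), (v, u)):
                if role_match(a, b):
                    sig = (a.id, edge.category, b.id)
                    if sig not in seen:
                        seen.add(sig)
                        out.append((a, edge, b))
                    break  # one orientation per edge
        out.sort(key=lambda t: (t[0].key, t[1].category, t[2].key))
        return out

    # ------------------------------------------------------------- convenience

    def neighbors_by_category(
        self, nid: str, category: str, neighbor_label: str | None = None
    ) -> list[Node]:
        """Undirected neighbours of a node reached through ``category``."""
        out = []
        for edge in self.edges_touching(nid):
            if edge.category != category:
                continue
            other = edge.target if edge.source == nid else edge.source
            node = self.get_node(other)
            if neighbor_label is None or node.label == neighbor_label:
                out.append(node)
        return sorted(out, key=lambda n: n.key)
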