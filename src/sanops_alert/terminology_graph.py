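"""Data model and I/O for anatomic terminology graphs.

A terminology is a set of named concepts joined by typed directed edges.
Four edge types point "rootward" (child/part toward parent/whole):
``is_a``, ``part_of``, ``regional_part_of`` and ``constitutional_part_of``.
The fifth, ``has_part``, is asserted in the opposite, "leafward" direction
(whole toward part).  Connecting walks always traverse edges in their
asserted direction, which is what makes some organ-to-region routes require
a mix of relation types.

The rootward sub-graph must be acyclic; this is validated at load time.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Iterator
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx

from .errors import GraphValidationError, LookupError_

__all__ = [
    "RelationType",
    "ROOTWARD_RELATIONS",
    "Concept",
    "Edge",
    "TypedPath",
    "TerminologyGraph",
    "load_graph",
    "save_graph",
    "rootward_neighbors",
    "find_paths",
    "rootward_closure_avoiding",
]

DEFAULT_MAX_PATH_LENGTH = 15


class RelationType(str, Enum):
    """Closed enumeration of edge relation types."""

    IS_A = "is_a"
    PART_OF = "part_of"
    HAS_PART = "has_part"
    REGIONAL_PART_OF = "regional_part_of"
    CONSTITUTIONAL_PART_OF = "constitutional_part_of"


#: Relations asserted child/part -> parent/whole.  HAS_PART is the lone
#: leafward relation (asserted whole -> part).
ROOTWARD_RELATIONS = frozenset(
    {
        RelationType.IS_A,
        RelationType.PART_OF,
        RelationType.REGIONAL_PART_OF,
        RelationType.CONSTITUTIONAL_PART_OF,
    }
)


@dataclass(frozen=True)
class Concept:
    """One named entity in a terminology.

    The owning-terminology name is carried for provenance but excluded
    from equality, so structural comparison survives serialization.
    """

    id: str
    label: str
    terminology: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError("concept id must be non-empty")
        if not self.label:
            raise GraphValidationError(f"concept {self.id!r} has an empty label")


@dataclass(frozen=True)
class Edge:
    """A typed directed edge, stored in its asserted direction."""

    source: str
    target: str
    relation: RelationType

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise GraphValidationError(
                f"self-loop on concept {self.source!r} is not allowed"
            )

    @property
    def rootward(self) -> bool:
        return self.relation in ROOTWARD_RELATIONS


@dataclass(frozen=True)
class TypedPath:
    """A chained sequence of edge traversals between two concepts."""

    edges: tuple[Edge, ...]

    def __post_init__(self) -> None:
        if not self.edges:
            raise GraphValidationError("a path must contain at least one edge")
        for prev, nxt in zip(self.edges, self.edges[1:]):
            if prev.target != nxt.source:
                raise GraphValidationError("path edges do not chain")

    @property
    def start(self) -> str:
        return self.edges[0].source

    @property
    def end(self) -> str:
        return self.edges[-1].target

    @property
    def relation_set(self) -> frozenset[RelationType]:
        return frozenset(e.relation for e in self.edges)

    @property
    def uniform(self) -> bool:
        """True when every edge shares one relation type."""
        return len(self.relation_set) == 1

    def concepts(self) -> tuple[str, ...]:
        return (self.edges[0].source,) + tuple(e.target for e in self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __str__(self) -> str:
        parts = [self.edges[0].source]
        for e in self.edges:
            parts.append(f"--{e.relation.value}-->")
            parts.append(e.target)
        return " ".join(parts)


class TerminologyGraph:
    """A named terminology: concepts plus typed directed edges.

    Invariants (checked by :meth:`validate`): every edge endpoint resolves
    to a concept, and the rootward sub-graph is acyclic.
    """

    def __init__(
        self,
        name: str,
        concepts: Iterable[Concept] = (),
        edges: Iterable[Edge] = (),
        validate: bool = True,
    ) -> None:
        self.name = name
        self._concepts: dict[str, Concept] = {}
        self._edges: set[Edge] = set()
        for c in concepts:
            self.add_concept(c)
        for e in edges:
            self.add_edge(e, validate=False)
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------

    def add_concept(self, concept: Concept) -> None:
        if concept.id in self._concepts:
            raise GraphValidationError(
                f"duplicate concept id {concept.id!r} in {self.name!r}"
            )
        self._concepts[concept.id] = concept

    def add_edge(self, edge: Edge, validate: bool = True) -> None:
        self._edges.add(edge)
        if validate:
            self.validate()

    # -- accessors --------------------------------------------------------

    @property
    def concepts(self) -> list[Concept]:
        return sorted(self._concepts.values(), key=lambda c: c.id)

    @property
    def edges(self) -> list[Edge]:
        return sorted(
            self._edges, key=lambda e: (e.source, e.target, e.relation.value)
        )

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __len__(self) -> int:
        return len(self._concepts)

    def concept(self, concept_id: str) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise LookupError_(
                f"unknown concept {concept_id!r} in terminology {self.name!r}"
            ) from None

    def by_label(self, label: str) -> Concept:
        """Look a concept up by its human-readable label (must be unique)."""
        hits = [c for c in self._concepts.values() if c.label == label]
        if len(hits) != 1:
            raise LookupError_(
                f"label {label!r} matches {len(hits)} concepts in {self.name!r}"
            )
        return hits[0]

    def out_edges(self, concept_id: str) -> Iterator[Edge]:
        self.concept(concept_id)
        for e in self._edges:
            if e.source == concept_id:
                yield e

    # -- derived graphs ---------------------------------------------------

    def as_digraph(self, rootward_only: bool = False) -> nx.MultiDiGraph:
        """Directed multigraph over asserted edge directions."""
        g = nx.MultiDiGraph()
        g.add_nodes_from(self._concepts)
        for e in self._edges:
            if rootward_only and not e.rootward:
                continue
            g.add_edge(e.source, e.target, relation=e.relation)
        return g

    def roots(self) -> set[str]:
        """Concepts with no outgoing rootward edge."""
        non_roots = {e.source for e in self._edges if e.rootward}
        return set(self._concepts) - non_roots

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for e in self._edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self._concepts:
                    raise GraphValidationError(
                        f"edge {e.source!r} -[{e.relation.value}]-> {e.target!r} "
                        f"references missing concept {endpoint!r}"
                    )
        rootward = self.as_digraph(rootward_only=True)
        try:
            cycle = nx.find_cycle(rootward)
        except nx.NetworkXNoCycle:
            return
        chain = " -> ".join(str(u) for u, _v, _k in cycle)
        raise GraphValidationError(f"rootward cycle detected: {chain}")

    # -- equality ---------------------------------------------------------

    def structurally_equal(self, other: "TerminologyGraph") -> bool:
        return (
            self.name == other.name
            and self.concepts == other.concepts
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return (
            f"TerminologyGraph({self.name!r}, {len(self._concepts)} concepts, "
            f"{len(self._edges)} edges)"
        )


# -- serialization --------------------------------------------------------


def load_graph(path: str | Path) -> TerminologyGraph:
    """Load a terminology graph from the package's JSON dialect.

    The file is a single object ``{"name", "concepts", "edges"}``; see
    :func:`save_graph` for the exact shape.  Raises
    :class:`GraphValidationError` for dangling edge endpoints or rootward
    cycles, ``json.JSONDecodeError`` for malformed JSON.
    """
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return graph_from_dict(payload)


def graph_from_dict(payload: dict) -> TerminologyGraph:
    for key in ("name", "concepts", "edges"):
        if key not in payload:
            raise GraphValidationError(f"ontology JSON missing key {key!r}")
    name = payload["name"]
    concepts = [
        Concept(id=c["id"], label=c["label"], terminology=name)
        for c in payload["concepts"]
    ]
    try:
        edges = [
            Edge(
                source=e["source"],
                target=e["target"],
                relation=RelationType(e["relation"]),
            )
            for e in payload["edges"]
        ]
    except ValueError as exc:
        raise GraphValidationError(f"unknown relation type: {exc}") from None
    return TerminologyGraph(name, concepts, edges)


def graph_to_dict(graph: TerminologyGraph) -> dict:
    return {
        "name": graph.name,
        "concepts": [{"id": c.id, "label": c.label} for c in graph.concepts],
        "edges": [
            {"source": e.source, "target": e.target, "relation": e.relation.value}
            for e in graph.edges
        ],
    }


def save_graph(graph: TerminologyGraph, path: str | Path) -> None:
    """Write ``graph`` as UTF-8 JSON with stable concept/edge ordering."""
    graph.validate()
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(graph_to_dict(graph), fh, indent=2, ensure_ascii=False)
        fh.write("\n")


# -- traversal ------------------------------------------------------------


def rootward_neighbors(
    graph: TerminologyGraph, concept_id: str
) -> set[tuple[str, RelationType]]:
    """Concepts one asserted rootward step away from ``concept_id``."""
    return {
        (e.target, e.relation) for e in graph.out_edges(concept_id) if e.rootward
    }


def find_paths(
    graph: TerminologyGraph,
    start: str,
    goal: str,
    max_length: int = DEFAULT_MAX_PATH_LENGTH,
) -> list[TypedPath]:
    """Enumerate simple connecting walks from ``start`` to ``goal``.

    Every edge is traversed in its asserted direction; walks never revisit
    a concept and contain at most ``max_length`` edges.  Returns an empty
    list when no walk exists.
    """
    graph.concept(start)
    graph.concept(goal)
    if max_length < 1:
        raise ValueError("max_length must be >= 1")

    adjacency: dict[str, list[Edge]] = {}
    for e in graph.edges:
        adjacency.setdefault(e.source, []).append(e)

    paths: list[TypedPath] = []
    stack: list[Edge] = []
    visited = {start}

    def dfs(node: str) -> None:
        if len(stack) >= max_length:
            return
        for edge in adjacency.get(node, ()):
            if edge.target in visited:
                continue
            stack.append(edge)
            if edge.target == goal:
                paths.append(TypedPath(tuple(stack)))
            else:
                visited.add(edge.target)
                dfs(edge.target)
                visited.remove(edge.target)
            stack.pop()

    dfs(start)
    paths.sort(key=lambda p: (len(p), str(p)))
    return paths


def rootward_closure_avoiding(
    graph: TerminologyGraph, start: str, forbidden: str
) -> bool:
    """True iff some maximal rootward walk from ``start`` reaches a root
    without ever visiting ``forbidden``.

    A root is a concept with no outgoing rootward edges; a start concept
    that is itself a root vacuously avoids any other forbidden concept.
    """
    graph.concept(start)
    if start == forbidden:
        return False
    roots = graph.roots()
    rootward = graph.as_digraph(rootward_only=True)
    if forbidden in rootward:
        rootward.remove_node(forbidden)
    reachable = {start} | nx.descendants(rootward, start)
    return bool(reachable & roots)
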