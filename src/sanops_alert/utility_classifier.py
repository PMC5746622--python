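"""Ordinal 1-5 utility classification of an exam's anatomic mapping.

Given an exam mapped into a candidate terminology, the classifier grades
how much extra machinery the terminology needs (beyond a plain region
lookup) to recover the exam's major body region(s):

1. a region/joint/whole-extremity marker sits directly on the exam's
   region or focus attribute — no graph work needed;
2. the focus reaches the marked region concept by a uniform-relation walk
   and no rootward walk bypasses it — a one-row lookup table suffices;
3. a uniform-relation walk exists but the polyhierarchy also offers
   rootward walks that bypass the region — lookup plus verification;
4. the focus connects to the region only through walks mixing relation
   types — a custom traversal algorithm is required;
5. no connecting walk exists at all.

Criteria are evaluated in order; the first match wins.  Exams naming
several regions are graded per region and the worst (highest) class is
reported, with per-region detail retained.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import ClassificationError, GraphValidationError, SanopsError
from .sanops_model import EXTREMITY_LIMBS, REGION_CODES
from .terminology_graph import (
    DEFAULT_MAX_PATH_LENGTH,
    RelationType,
    TerminologyGraph,
    TypedPath,
    find_paths,
    rootward_closure_avoiding,
)

__all__ = [
    "Marker",
    "CorrespondenceTable",
    "ExamAnatomicMapping",
    "RegionResult",
    "UtilityClass",
    "classify",
    "classify_oracle",
    "classify_batch",
]

_RATIONALES = {
    1: "class 1: a region/joint/whole-extremity marker sits directly on the "
       "exam's region or focus attribute",
    2: "class 2: uniform-relation walk from focus to the marked region "
       "concept with no bypassing rootward walk",
    3: "class 3: uniform-relation walk from focus to the marked region "
       "concept, but rootward walks bypass it (polyhierarchy)",
    4: "class 4: focus connects to the marked region concept only through "
       "walks mixing relation types",
    5: "class 5: no connecting walk from focus to the marked region concept",
}


@dataclass(frozen=True)
class Marker:
    """Annotation tying one terminology concept to the region model.

    ``kind`` is ``SANOPS`` (the concept IS a major region), ``JOINT`` (a
    large extremity joint standing in for one extremity region), or
    ``WHOLE_EXTREMITY`` (a whole-limb concept covering that limb's three
    regions).
    """

    kind: str
    value: str

    def __post_init__(self) -> None:
        if self.kind in ("SANOPS", "JOINT"):
            if self.value not in REGION_CODES:
                raise SanopsError(f"unknown region code {self.value!r}")
        elif self.kind == "WHOLE_EXTREMITY":
            if self.value not in EXTREMITY_LIMBS:
                raise SanopsError(f"unknown limb {self.value!r}")
        else:
            raise SanopsError(f"unknown marker kind {self.kind!r}")

    @property
    def regions(self) -> frozenset[str]:
        """Region codes this marker resolves to."""
        if self.kind == "WHOLE_EXTREMITY":
            return frozenset(EXTREMITY_LIMBS[self.value])
        return frozenset({self.value})

    def __str__(self) -> str:
        return f"{self.kind}:{self.value}"

    @classmethod
    def parse(cls, text: str) -> "Marker":
        kind, _, value = text.partition(":")
        if not value:
            raise SanopsError(f"malformed marker {text!r}")
        return cls(kind, value)


class CorrespondenceTable:
    """Concept id -> marker, for one terminology."""

    def __init__(self, markers: dict[str, Marker] | None = None) -> None:
        self._markers: dict[str, Marker] = dict(markers or {})

    def marker(self, concept_id: str) -> Marker | None:
        return self._markers.get(concept_id)

    def set(self, concept_id: str, marker: Marker) -> None:
        self._markers[concept_id] = marker

    def region_concept(self, region_code: str) -> str | None:
        """The concept carrying the SANOPS marker for ``region_code``."""
        hits = [
            cid
            for cid, m in self._markers.items()
            if m.kind == "SANOPS" and m.value == region_code
        ]
        if len(hits) > 1:
            raise SanopsError(
                f"region {region_code!r} marked on multiple concepts: {hits}"
            )
        return hits[0] if hits else None

    def items(self):
        return sorted(self._markers.items())

    def __len__(self) -> int:
        return len(self._markers)

    def validate_against(self, graph: TerminologyGraph) -> None:
        for cid in self._markers:
            graph.concept(cid)

    @classmethod
    def from_csv(cls, path: str | Path, terminology: str | None = None
                 ) -> "CorrespondenceTable":
        """Read (terminology, concept_id, marker) rows; optionally filter."""
        table = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                if terminology and row["terminology"] != terminology:
                    continue
                table.set(row["concept_id"], Marker.parse(row["marker"]))
        return table

    def to_csv(self, path: str | Path, terminology: str) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["terminology", "concept_id", "marker"])
            for cid, marker in self.items():
                writer.writerow([terminology, cid, str(marker)])


def _as_tuple(value) -> tuple[str, ...]:
    if value is None:
        return ()
    if isinstance(value, str):
        return (value,)
    return tuple(value)


@dataclass(frozen=True)
class ExamAnatomicMapping:
    """One exam code's anatomic assignment within one terminology.

    ``region_attribute`` holds the body-region / region-imaged / system
    attribute concept(s) declared by the exam code, ``focus_attribute``
    the narrower anatomic-focus concept(s); at least one must be present.
    ``target_regions`` are the region codes named by the exam's long
    common name, supplied with the mapping (they are modelling facts, not
    derivable from graph structure).
    """

    exam_code: str
    exam_name: str
    terminology: str
    region_attribute: tuple[str, ...] = ()
    focus_attribute: tuple[str, ...] = ()
    target_regions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "region_attribute", _as_tuple(self.region_attribute)
        )
        object.__setattr__(
            self, "focus_attribute", _as_tuple(self.focus_attribute)
        )
        object.__setattr__(
            self, "target_regions", _as_tuple(self.target_regions)
        )
        if not self.region_attribute and not self.focus_attribute:
            raise GraphValidationError(
                f"mapping for {self.exam_code!r} has neither a region nor a "
                "focus attribute"
            )

    @property
    def attributes(self) -> tuple[str, ...]:
        return self.region_attribute + self.focus_attribute

    @property
    def walk_sources(self) -> tuple[str, ...]:
        """Concepts from which connecting walks are traced (focus if
        present, else the region attribute itself)."""
        return self.focus_attribute or self.region_attribute


@dataclass(frozen=True)
class RegionResult:
    """Classification outcome for one target region."""

    region: str
    value: int | None
    rationale: str
    witness: TypedPath | None = None
    error: str | None = None


@dataclass(frozen=True)
class UtilityClass:
    """Aggregate ordinal score for one (terminology, exam) mapping."""

    value: int
    rationale: str
    witness: TypedPath | None = None
    per_region: tuple[RegionResult, ...] = ()

    def __post_init__(self) -> None:
        if self.value not in (1, 2, 3, 4, 5):
            raise SanopsError(f"utility class must be 1..5, got {self.value}")
        if not self.rationale:
            raise SanopsError("utility class rationale must be non-empty")


def _attribute_markers(
    mapping: ExamAnatomicMapping, table: CorrespondenceTable
) -> list[Marker]:
    return [
        m for cid in mapping.attributes if (m := table.marker(cid)) is not None
    ]


def _uniform_witness(
    graph: TerminologyGraph, start: str, goal: str, max_length: int
) -> TypedPath | None:
    """Shortest single-relation-type walk start -> goal, if any."""
    best: TypedPath | None = None
    for relation in RelationType:
        sub = nx.DiGraph()
        sub.add_nodes_from(c.id for c in graph.concepts)
        for e in graph.edges:
            if e.relation is relation:
                sub.add_edge(e.source, e.target)
        try:
            nodes = nx.shortest_path(sub, start, goal)
        except nx.NetworkXNoPath:
            continue
        if len(nodes) - 1 > max_length:
            continue
        from .terminology_graph import Edge

        path = TypedPath(
            tuple(
                Edge(a, b, relation) for a, b in zip(nodes, nodes[1:])
            )
        )
        if best is None or len(path) < len(best):
            best = path
    return best


def _any_witness(
    graph: TerminologyGraph, start: str, goal: str, max_length: int
) -> TypedPath | None:
    """Shortest connecting walk start -> goal (any relation mix), if any."""
    paths = find_paths(graph, start, goal, max_length)
    return paths[0] if paths else None


def _classify_region(
    graph: TerminologyGraph,
    mapping: ExamAnatomicMapping,
    table: CorrespondenceTable,
    region: str,
    max_length: int,
) -> RegionResult:
    # criterion 1: a marker on any attribute resolving to this region
    for cid in mapping.attributes:
        marker = table.marker(cid)
        if marker is not None and region in marker.regions:
            return RegionResult(region, 1, _RATIONALES[1])

    target = table.region_concept(region)
    if target is None or target not in graph:
        return RegionResult(
            region, None, "no target region",
            error=f"no concept carries the SANOPS:{region} marker",
        )

    best: RegionResult | None = None
    for focus in mapping.walk_sources:
        if focus not in graph:
            continue
        uniform = _uniform_witness(graph, focus, target, max_length)
        if uniform is not None:
            bypass = rootward_closure_avoiding(graph, focus, target)
            value = 3 if bypass else 2
            result = RegionResult(region, value, _RATIONALES[value], uniform)
        else:
            witness = _any_witness(graph, focus, target, max_length)
            if witness is not None:
                result = RegionResult(region, 4, _RATIONALES[4], witness)
            else:
                result = RegionResult(region, 5, _RATIONALES[5])
        if best is None or result.value < best.value:
            best = result
    if best is None:
        best = RegionResult(region, 5, _RATIONALES[5])
    return best


def classify(
    graph: TerminologyGraph,
    mapping: ExamAnatomicMapping,
    table: CorrespondenceTable,
    max_length: int = DEFAULT_MAX_PATH_LENGTH,
) -> UtilityClass:
    """Grade one exam mapping on the 1-5 utility scale.

    Raises :class:`ClassificationError` when no target region is
    resolvable at all — no marker on any attribute and no marked region
    concept to walk to.  That situation is distinct from class 5, where a
    target exists but cannot be reached.
    """
    markers = _attribute_markers(mapping, table)
    if not mapping.target_regions:
        if markers:
            return UtilityClass(1, _RATIONALES[1])
        raise ClassificationError(
            f"exam {mapping.exam_code!r}: no target region — no attribute "
            "marker and no region named for the exam"
        )

    results = [
        _classify_region(graph, mapping, table, region, max_length)
        for region in mapping.target_regions
    ]
    classified = [r for r in results if r.value is not None]
    if not classified and not markers:
        raise ClassificationError(
            f"exam {mapping.exam_code!r}: no target region resolvable "
            f"({'; '.join(r.error or '' for r in results)})"
        )
    if not classified:
        # markers exist but none match the named regions and no region
        # concept is marked; the markers still give a direct lookup
        return UtilityClass(1, _RATIONALES[1], per_region=tuple(results))
    worst = max(classified, key=lambda r: r.value)
    return UtilityClass(
        worst.value, worst.rationale, worst.witness, tuple(results)
    )


# -- independent brute-force reference ------------------------------------


def _enumerate_walks(
    graph: TerminologyGraph,
    start: str,
    rootward_only: bool,
    max_length: int | None,
) -> list[tuple]:
    """All simple walks from ``start`` as edge tuples (pure enumeration)."""
    edges = graph.edges
    walks: list[tuple] = []

    def extend(walk: tuple, visited: frozenset) -> None:
        if max_length is not None and len(walk) >= max_length:
            return
        tail = walk[-1].target if walk else start
        for e in edges:
            if e.source != tail or e.target in visited:
                continue
            if rootward_only and not e.rootward:
                continue
            new = walk + (e,)
            walks.append(new)
            extend(new, visited | {e.target})

    extend((), frozenset({start}))
    return walks


def classify_oracle(
    graph: TerminologyGraph,
    mapping: ExamAnatomicMapping,
    table: CorrespondenceTable,
    max_length: int = DEFAULT_MAX_PATH_LENGTH,
) -> UtilityClass:
    """Reference classifier by exhaustive walk enumeration (no pruning).

    Same contract as :func:`classify`; restricted to graphs of at most 40
    concepts to keep full enumeration tractable.
    """
    if len(graph) > 40:
        raise SanopsError(
            f"oracle limited to graphs of <= 40 concepts, got {len(graph)}"
        )
    markers = _attribute_markers(mapping, table)
    if not mapping.target_regions:
        if markers:
            return UtilityClass(1, _RATIONALES[1])
        raise ClassificationError(
            f"exam {mapping.exam_code!r}: no target region"
        )

    roots = graph.roots()
    results: list[RegionResult] = []
    for region in mapping.target_regions:
        matched = any(
            (m := table.marker(cid)) is not None and region in m.regions
            for cid in mapping.attributes
        )
        if matched:
            results.append(RegionResult(region, 1, _RATIONALES[1]))
            continue
        target = table.region_concept(region)
        if target is None or target not in graph:
            results.append(
                RegionResult(region, None, "no target region",
                             error="unmarked region")
            )
            continue
        value = 5
        for focus in mapping.walk_sources:
            if focus not in graph:
                continue
            walks = _enumerate_walks(graph, focus, False, max_length)
            connecting = [w for w in walks if w[-1].target == target]
            uniform = [
                w for w in connecting if len({e.relation for e in w}) == 1
            ]
            rootward_walks = _enumerate_walks(graph, focus, True, None)
            maximal = [
                w for w in rootward_walks if w[-1].target in roots
            ]
            if focus in roots and focus != target:
                bypass = True
            else:
                bypass = any(
                    target not in {e.target for e in w} for w in maximal
                )
            if uniform:
                value = min(value, 3 if bypass else 2)
            elif connecting:
                value = min(value, 4)
        results.append(RegionResult(region, value, _RATIONALES[value]))

    classified = [r for r in results if r.value is not None]
    if not classified and not markers:
        raise ClassificationError(
            f"exam {mapping.exam_code!r}: no target region resolvable"
        )
    if not classified:
        return UtilityClass(1, _RATIONALES[1], per_region=tuple(results))
    worst = max(classified, key=lambda r: r.value)
    return UtilityClass(
        worst.value, worst.rationale, per_region=tuple(results)
    )


def classify_batch(
    graph: TerminologyGraph,
    mappings: list[ExamAnatomicMapping],
    table: CorrespondenceTable,
    max_length: int = DEFAULT_MAX_PATH_LENGTH,
) -> list[tuple[str, UtilityClass | ClassificationError]]:
    """Classify many mappings; per-row errors are collected, not raised."""
    out: list[tuple[str, UtilityClass | ClassificationError]] = []
    for mapping in mappings:
        try:
            out.append(
                (mapping.exam_code, classify(graph, mapping, table, max_length))
            )
        except ClassificationError as exc:
            out.append((mapping.exam_code, exc))
    return out
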