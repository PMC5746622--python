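"""Built-in mini-terminologies, the scenario table, and random generators.

Each fixture encodes only the structural facts of the source terminology
that matter for the worked examples and the seven firing scenarios: how
each terminology files (or fails to file) an organ under its containing
body region.  Facts not needed for those cases are deliberately absent —
absence of a link yields class 5 / no alert, which is the behaviour being
modelled.  Concept ids are synthetic; no excerpt of any real terminology
release is shipped.

Exam codes are placeholders (``CTX-nnn``) except Liver CT, which uses its
published LOINC code 24815-3.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .alert_engine import TerminologyBackend
from .errors import LookupError_, SpecError
from .sanops_model import AlertClass, default_regions
from .terminology_graph import (
    Concept,
    Edge,
    RelationType,
    TerminologyGraph,
)
from .utility_classifier import (
    CorrespondenceTable,
    ExamAnatomicMapping,
    Marker,
)

__all__ = [
    "FIXTURE_NAMES",
    "EXAMS",
    "FixtureBundle",
    "ScenarioRow",
    "PlantedGraphSpec",
    "build_fixture",
    "scenario_table",
    "random_terminology",
    "random_class_sample",
]

FIXTURE_NAMES = ("loinc", "loinc_rsna", "radlex", "fma", "snomed", "sanops")

#: Shared exam catalogue: code -> (long name, region codes named by the exam).
#: Only the Liver CT code is a published LOINC code; the rest are synthetic.
EXAMS: dict[str, tuple[str, tuple[str, ...]]] = {
    "CTX-001": ("Head CT with IV contrast", ("1",)),
    "CTX-002": ("Head CT without IV contrast", ("1",)),
    "CTX-003": ("Neck CT without IV contrast", ("2",)),
    "CTX-004": ("Elbow - bilateral CT without contrast", ("6b", "7b")),
    "CTX-005": ("Shoulder - right CT with contrast IV", ("7a",)),
    "CTX-006": ("Paranasal sinuses CT without IV contrast", ("1",)),
    "24815-3": ("Liver CT", ("4",)),
    "CTX-008": ("Kidney CT without and with contrast IV", ("4",)),
    "CTX-009": ("Cervical spine CT", ("2",)),
    "CTX-010": ("Chest CT", ("3",)),
    "CTX-011": ("Esophagus CT", ("3",)),
    "CTX-012": ("Abdomen and Pelvis CT", ("4", "5")),
    "CTX-013": ("Right Knee CT", ("9b",)),
    "CTX-014": ("CT angio abdomen", ("4",)),
    "CTX-015": ("Neck vessel CT angio", ("2",)),
    "CTX-016": ("Temporal bone CT", ("1",)),
}


@dataclass
class FixtureBundle:
    """A backend plus a per-edge note of the structural fact it encodes."""

    backend: TerminologyBackend
    provenance: dict[Edge, str] = field(default_factory=dict)

    def validate(self) -> None:
        self.backend.validate()
        for edge in self.backend.graph.edges:
            if edge not in self.provenance:
                raise SpecError(f"fixture edge without provenance note: {edge}")


@dataclass(frozen=True)
class ScenarioRow:
    """One hypothetical firing scenario with its expected outcome."""

    number: int
    prior_code: str
    prior_name: str
    current_code: str
    current_name: str
    expected_fire: frozenset[str]
    expected_type: AlertClass | None


def scenario_table() -> list[ScenarioRow]:
    """The seven firing scenarios and which terminologies should fire.

    Rows 1-3 fire in every column (similar for row 1, proximate for rows
    2-3); row 4 fires only for the playbook and radlex backends (similar);
    row 5 only for radlex (similar); rows 6-7 fire nowhere.
    """
    all_five = frozenset({"loinc", "loinc_rsna", "radlex", "fma", "snomed"})

    def row(n, prior, current, fire, kind):
        return ScenarioRow(
            number=n,
            prior_code=prior,
            prior_name=EXAMS[prior][0],
            current_code=current,
            current_name=EXAMS[current][0],
            expected_fire=frozenset(fire),
            expected_type=kind,
        )

    return [
        row(1, "CTX-001", "CTX-002", all_five, AlertClass.SIMILAR),
        row(2, "CTX-001", "CTX-003", all_five, AlertClass.PROXIMATE),
        row(3, "CTX-004", "CTX-005", all_five, AlertClass.PROXIMATE),
        row(4, "CTX-001", "CTX-006", {"loinc_rsna", "radlex"},
            AlertClass.SIMILAR),
        row(5, "24815-3", "CTX-008", {"radlex"}, AlertClass.SIMILAR),
        row(6, "CTX-009", "CTX-003", frozenset(), None),
        row(7, "CTX-011", "CTX-010", frozenset(), None),
    ]


# -- fixture construction --------------------------------------------------

_R = RelationType

# Region-level concepts present in every candidate fixture, with their
# region markers; joint concepts likewise (a large joint stands in for the
# extremity region it anchors).
_REGION_CONCEPTS = {
    "Head": "SANOPS:1",
    "Neck": "SANOPS:2",
    "Chest": "SANOPS:3",
    "Abdomen": "SANOPS:4",
    "Pelvis": "SANOPS:5",
}
_JOINT_CONCEPTS = {
    "LeftElbow": ("Left elbow", "JOINT:6b"),
    "RightElbow": ("Right elbow", "JOINT:7b"),
    "RightShoulder": ("Right shoulder", "JOINT:7a"),
    "RightKnee": ("Right knee", "JOINT:9b"),
}


class _Builder:
    """Accumulates one fixture's concepts, edges, markers and mappings."""

    def __init__(self, name: str, prefix: str) -> None:
        self.name = name
        self.prefix = prefix
        self.concepts: list[Concept] = []
        self.edges: list[Edge] = []
        self.notes: dict[Edge, str] = {}
        self.table = CorrespondenceTable()
        self.mappings: dict[str, ExamAnatomicMapping] = {}

    def cid(self, key: str) -> str:
        return f"{self.prefix}:{key}"

    def concept(self, key: str, label: str, marker: str | None = None) -> str:
        full = self.cid(key)
        self.concepts.append(Concept(full, label, self.name))
        if marker:
            self.table.set(full, Marker.parse(marker))
        return full

    def edge(self, src: str, rel: RelationType, dst: str, note: str) -> None:
        e = Edge(self.cid(src), self.cid(dst), rel)
        self.edges.append(e)
        self.notes[e] = note

    def map_exam(self, code: str, region=(), focus=()) -> None:
        name, targets = EXAMS[code]
        self.mappings[code] = ExamAnatomicMapping(
            exam_code=code,
            exam_name=name,
            terminology=self.name,
            region_attribute=tuple(self.cid(k) for k in _as_seq(region)),
            focus_attribute=tuple(self.cid(k) for k in _as_seq(focus)),
            target_regions=targets,
        )

    def bundle(self) -> FixtureBundle:
        graph = TerminologyGraph(self.name, self.concepts, self.edges)
        backend = TerminologyBackend(
            self.name, graph, self.mappings, self.table
        )
        fb = FixtureBundle(backend, self.notes)
        fb.validate()
        return fb


def _as_seq(value) -> tuple[str, ...]:
    if isinstance(value, str):
        return (value,)
    return tuple(value)


def _add_shared_concepts(b: _Builder, region_label=lambda label: label) -> None:
    for key, marker in _REGION_CONCEPTS.items():
        b.concept(key, region_label(key), marker)
    for key, (label, marker) in _JOINT_CONCEPTS.items():
        b.concept(key, region_label(label), marker)


def _build_loinc() -> FixtureBundle:
    b = _Builder("loinc", "LOINC")
    _add_shared_concepts(b)
    b.concept("SkeletalSystem", "Skeletal system")
    b.concept("UrinarySystem", "Urinary system")
    b.concept("GISystem", "Gastrointestinal system")
    b.concept("ParanasalSinuses", "Paranasal sinuses")
    b.concept("AbdominalVessels", "Abdominal vessels")
    b.concept("CervicalSpine", "Cervical spine")
    b.concept("Liver", "Liver")
    b.concept("Kidney", "Kidney")
    b.concept("Esophagus", "Esophagus")
    b.concept("TemporalBone", "Temporal bone")
    b.concept("NeckVessels", "Neck vessels")

    b.edge("ParanasalSinuses", _R.IS_A, "SkeletalSystem",
           "LOINC files paranasal sinuses under the skeletal system, with "
           "no link to head")
    b.edge("AbdominalVessels", _R.IS_A, "Abdomen",
           "LOINC nests abdominal vessels directly under abdomen")
    b.edge("CervicalSpine", _R.IS_A, "SkeletalSystem",
           "LOINC links cervical spine to the skeletal system only, not to "
           "neck")
    b.edge("Liver", _R.IS_A, "Abdomen",
           "the LOINC system attribute Abdomen>Liver nests liver under "
           "abdomen")
    b.edge("Kidney", _R.IS_A, "UrinarySystem",
           "LOINC nests kidney under the urinary system with no link to "
           "abdomen")
    b.edge("Esophagus", _R.IS_A, "GISystem",
           "LOINC nests esophagus under an organ system, not under any "
           "body region")
    b.edge("TemporalBone", _R.IS_A, "SkeletalSystem",
           "LOINC files temporal bone under the skeletal system with no "
           "link to head")

    b.map_exam("CTX-001", focus="Head")
    b.map_exam("CTX-002", focus="Head")
    b.map_exam("CTX-003", focus="Neck")
    b.map_exam("CTX-004", focus=("LeftElbow", "RightElbow"))
    b.map_exam("CTX-005", focus="RightShoulder")
    b.map_exam("CTX-006", focus="ParanasalSinuses")
    b.map_exam("24815-3", focus="Liver")
    b.map_exam("CTX-008", focus="Kidney")
    b.map_exam("CTX-009", focus="CervicalSpine")
    b.map_exam("CTX-010", focus="Chest")
    b.map_exam("CTX-011", focus="Esophagus")
    b.map_exam("CTX-012", focus=("Abdomen", "Pelvis"))
    b.map_exam("CTX-013", focus="RightKnee")
    b.map_exam("CTX-014", focus="AbdominalVessels")
    b.map_exam("CTX-015", focus="NeckVessels")
    b.map_exam("CTX-016", focus="TemporalBone")
    return b.bundle()


def _build_playbook_like(name: str, prefix: str,
                         kidney_has_region: bool) -> FixtureBundle:
    """Common shape of the playbook and radlex fixtures: exams carry
    region-imaged / body-region attributes; they differ only in whether
    the kidney exam declares an abdomen region attribute."""
    b = _Builder(name, prefix)
    _add_shared_concepts(b)
    b.concept("CervicalSpine", "Cervical spine")
    b.concept("ParanasalSinuses", "Paranasal sinuses")
    b.concept("Liver", "Liver")
    b.concept("Kidney", "Kidney")
    b.concept("Esophagus", "Esophagus")
    b.concept("TemporalBone", "Temporal bone")
    b.concept("AbdominalVessels", "Abdominal vessels")
    b.concept("NeckVessels", "Neck vessels")

    b.edge("Liver", _R.PART_OF, "Abdomen",
           f"{name} links liver to abdomen")

    b.map_exam("CTX-001", region="Head")
    b.map_exam("CTX-002", region="Head")
    b.map_exam("CTX-003", region="Neck")
    b.map_exam("CTX-004", focus=("LeftElbow", "RightElbow"))
    b.map_exam("CTX-005", focus="RightShoulder")
    # head is declared as the region-imaged / body-region attribute of the
    # sinus exam, so the region is available with no graph work
    b.map_exam("CTX-006", region="Head", focus="ParanasalSinuses")
    b.map_exam("24815-3", region="Abdomen", focus="Liver")
    if kidney_has_region:
        b.map_exam("CTX-008", region="Abdomen", focus="Kidney")
    else:
        # kidney exam declares no region attribute and the terminology has
        # no link from kidney to abdomen
        b.map_exam("CTX-008", focus="Kidney")
    # the declared body region is the (unmarked) cervical spine itself
    b.map_exam("CTX-009", region="CervicalSpine", focus="CervicalSpine")
    b.map_exam("CTX-010", region="Chest")
    b.map_exam("CTX-011", focus="Esophagus")
    b.map_exam("CTX-012", region=("Abdomen", "Pelvis"))
    b.map_exam("CTX-013", focus="RightKnee")
    b.map_exam("CTX-014", region="Abdomen", focus="AbdominalVessels")
    b.map_exam("CTX-015", region="Neck", focus="NeckVessels")
    b.map_exam("CTX-016", focus="TemporalBone")
    return b.bundle()


def _build_fma() -> FixtureBundle:
    b = _Builder("fma", "FMA")
    _add_shared_concepts(b)
    b.concept("AnatomicalSpaces", "Anatomical spaces")
    b.concept("ParanasalSinuses", "Paranasal sinuses")
    b.concept("Liver", "Liver")
    b.concept("Kidney", "Kidney")
    b.concept("UrinarySystem", "Urinary system")
    b.concept("CervicalSpine", "Cervical spine")
    b.concept("VertebralColumn", "Vertebral column")
    b.concept("SkeletalSystem", "Skeletal system")
    b.concept("Esophagus", "Esophagus")
    b.concept("ThoracicEsophagus", "Thoracic esophagus")
    b.concept("Mediastinum", "Mediastinum")
    b.concept("TemporalBone", "Temporal bone")
    b.concept("AbdominalVessels", "Abdominal vasculature")
    b.concept("NeckVessels", "Vasculature of neck")

    b.edge("ParanasalSinuses", _R.IS_A, "AnatomicalSpaces",
           "the reference anatomy ontology subsumes paranasal sinuses "
           "under anatomical spaces, bypassing head")
    b.edge("Liver", _R.PART_OF, "Abdomen",
           "a homogeneous part_of link relates liver to abdomen")
    b.edge("Kidney", _R.CONSTITUTIONAL_PART_OF, "UrinarySystem",
           "kidney is filed as a constitutional part of the urinary "
           "system, with no link to abdomen")
    b.edge("CervicalSpine", _R.PART_OF, "Neck",
           "cervical spine is linked to the neck region by part_of")
    b.edge("CervicalSpine", _R.REGIONAL_PART_OF, "VertebralColumn",
           "cervical spine also links to the vertebral column, bypassing "
           "neck")
    b.edge("VertebralColumn", _R.PART_OF, "SkeletalSystem",
           "the vertebral column is part of the skeletal system")
    b.edge("Esophagus", _R.HAS_PART, "ThoracicEsophagus",
           "reaching chest from esophagus requires first travelling down "
           "a has_part link to thoracic esophagus")
    b.edge("ThoracicEsophagus", _R.PART_OF, "Mediastinum",
           "thoracic esophagus is part of the mediastinum")
    b.edge("Mediastinum", _R.PART_OF, "Chest",
           "the mediastinum is part of the chest, completing the mixed "
           "has_part/part_of route")

    b.map_exam("CTX-001", focus="Head")
    b.map_exam("CTX-002", focus="Head")
    b.map_exam("CTX-003", focus="Neck")
    b.map_exam("CTX-004", focus=("LeftElbow", "RightElbow"))
    b.map_exam("CTX-005", focus="RightShoulder")
    b.map_exam("CTX-006", focus="ParanasalSinuses")
    b.map_exam("24815-3", focus="Liver")
    b.map_exam("CTX-008", focus="Kidney")
    b.map_exam("CTX-009", focus="CervicalSpine")
    b.map_exam("CTX-010", focus="Chest")
    b.map_exam("CTX-011", focus="Esophagus")
    b.map_exam("CTX-012", focus=("Abdomen", "Pelvis"))
    b.map_exam("CTX-013", focus="RightKnee")
    b.map_exam("CTX-014", focus="AbdominalVessels")
    b.map_exam("CTX-015", focus="NeckVessels")
    b.map_exam("CTX-016", focus="TemporalBone")
    return b.bundle()


def _build_snomed() -> FixtureBundle:
    b = _Builder("snomed", "SCT")
    _add_shared_concepts(b, region_label=lambda label: f"{label} structure")
    b.concept("BoneOfHead", "Bone structure of head")
    b.concept("SkeletalSystem", "Skeletal system structure")
    b.concept("TemporalBone", "Temporal bone structure")
    b.concept("ParanasalSinuses", "Paranasal sinus structure")
    b.concept("BodyCavity", "Body cavity structure")
    b.concept("Liver", "Liver structure")
    b.concept("Kidney", "Kidney structure")
    b.concept("DigestiveOrgan", "Digestive organ structure")
    b.concept("UrinarySystem", "Urinary system structure")
    b.concept("CervicalSpine", "Cervical spine structure")
    b.concept("VertebralColumn", "Vertebral column structure")
    b.concept("Esophagus", "Esophagus structure")
    b.concept("AbdominalVessels", "Abdominal vessel structure")
    b.concept("NeckVessels", "Neck vessel structure")

    b.edge("TemporalBone", _R.IS_A, "BoneOfHead",
           "one is_a route from temporal bone leads toward head")
    b.edge("BoneOfHead", _R.IS_A, "Head",
           "bones of the head subsume under the head structure")
    b.edge("TemporalBone", _R.IS_A, "SkeletalSystem",
           "a second is_a route from temporal bone reaches the skeletal "
           "system, bypassing head")
    b.edge("ParanasalSinuses", _R.IS_A, "Head",
           "some hierarchies nest paranasal sinuses under head")
    b.edge("ParanasalSinuses", _R.IS_A, "BodyCavity",
           "other hierarchies bypass head on the way to a different "
           "superclass")
    b.edge("Liver", _R.IS_A, "Abdomen",
           "SEP-style is_a links relate liver to the abdominal structure")
    b.edge("Liver", _R.IS_A, "DigestiveOrgan",
           "divergent is_a links from liver bypass abdomen")
    b.edge("Kidney", _R.IS_A, "Abdomen",
           "SEP-style is_a links relate kidney to the abdominal structure")
    b.edge("Kidney", _R.IS_A, "UrinarySystem",
           "divergent is_a links from kidney bypass abdomen")
    b.edge("CervicalSpine", _R.IS_A, "Neck",
           "cervical spine links to the neck structure")
    b.edge("CervicalSpine", _R.IS_A, "VertebralColumn",
           "cervical spine also links to the vertebral column, bypassing "
           "neck")
    b.edge("Esophagus", _R.IS_A, "Chest",
           "esophagus links to the thoracic structure")
    b.edge("Esophagus", _R.IS_A, "DigestiveOrgan",
           "divergent is_a links from esophagus bypass chest")

    b.map_exam("CTX-001", focus="Head")
    b.map_exam("CTX-002", focus="Head")
    b.map_exam("CTX-003", focus="Neck")
    b.map_exam("CTX-004", focus=("LeftElbow", "RightElbow"))
    b.map_exam("CTX-005", focus="RightShoulder")
    b.map_exam("CTX-006", focus="ParanasalSinuses")
    b.map_exam("24815-3", focus="Liver")
    b.map_exam("CTX-008", focus="Kidney")
    b.map_exam("CTX-009", focus="CervicalSpine")
    b.map_exam("CTX-010", focus="Chest")
    b.map_exam("CTX-011", focus="Esophagus")
    b.map_exam("CTX-012", focus=("Abdomen", "Pelvis"))
    b.map_exam("CTX-013", focus="RightKnee")
    b.map_exam("CTX-014", focus="AbdominalVessels")
    b.map_exam("CTX-015", focus="NeckVessels")
    b.map_exam("CTX-016", focus="TemporalBone")
    return b.bundle()


def _build_sanops() -> FixtureBundle:
    """The reference backend: one concept per region, identity markers."""
    b = _Builder("sanops", "SAN")
    for region in default_regions():
        b.concept(region.code, region.label, f"SANOPS:{region.code}")

    assignments = {
        "CTX-001": "1", "CTX-002": "1", "CTX-003": "2",
        "CTX-004": ("6b", "7b"), "CTX-005": "7a", "CTX-006": "1",
        "24815-3": "4", "CTX-008": "4", "CTX-009": "2", "CTX-010": "3",
        "CTX-011": "3", "CTX-012": ("4", "5"), "CTX-013": "9b",
        "CTX-014": "4", "CTX-015": "2", "CTX-016": "1",
    }
    for code, regions in assignments.items():
        b.map_exam(code, region=regions)
    return b.bundle()


def build_fixture(name: str) -> FixtureBundle:
    """Build one of the six built-in fixture bundles by name."""
    builders = {
        "loinc": _build_loinc,
        "loinc_rsna": lambda: _build_playbook_like(
            "loinc_rsna", "LNR", kidney_has_region=False
        ),
        "radlex": lambda: _build_playbook_like(
            "radlex", "RADLEX", kidney_has_region=True
        ),
        "fma": _build_fma,
        "snomed": _build_snomed,
        "sanops": _build_sanops,
    }
    try:
        builder = builders[name]
    except KeyError:
        raise LookupError_(
            f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}"
        ) from None
    return builder()


def all_backends(include_sanops: bool = False) -> dict[str, TerminologyBackend]:
    """The five candidate backends (plus the reference one on request)."""
    names = FIXTURE_NAMES if include_sanops else FIXTURE_NAMES[:-1]
    return {name: build_fixture(name).backend for name in names}


# -- random generators -----------------------------------------------------

_DEFAULT_PALETTE = (
    RelationType.IS_A,
    RelationType.PART_OF,
    RelationType.HAS_PART,
)


@dataclass(frozen=True)
class PlantedGraphSpec:
    """Recipe for a random terminology with a known utility class."""

    seed: int
    n_concepts: int = 8
    planted_class: int = 2
    palette: tuple[RelationType, ...] = _DEFAULT_PALETTE

    def __post_init__(self) -> None:
        if self.n_concepts < 3:
            raise SpecError("n_concepts must be >= 3")
        if self.planted_class not in (1, 2, 3, 4, 5):
            raise SpecError("planted_class must be in 1..5")
        rootward = [r for r in self.palette if r is not RelationType.HAS_PART]
        if self.planted_class >= 2 and not rootward:
            raise SpecError(
                "classes 2-5 need at least one rootward relation in the "
                "palette"
            )
        if self.planted_class == 4 and (
            RelationType.HAS_PART not in self.palette or not rootward
        ):
            raise SpecError(
                "class 4 needs has_part plus a rootward relation in the "
                "palette"
            )


def random_terminology(
    spec: PlantedGraphSpec,
) -> tuple[TerminologyGraph, ExamAnatomicMapping, CorrespondenceTable]:
    """Generate a reproducible graph whose mapping classifies to the
    planted class by construction.

    The core motif (focus, target region concept, connecting structure)
    realises exactly the planted class; remaining concepts are decoration
    wired so that they can never add walks out of the focus.
    """
    rng = random.Random(spec.seed)
    rootward = [r for r in spec.palette if r is not RelationType.HAS_PART]
    uniform = rng.choice(rootward) if rootward else None

    name = f"planted-{spec.planted_class}-{spec.seed}"
    concepts: list[Concept] = []
    edges: list[Edge] = []
    table = CorrespondenceTable()

    def add(key: str, label: str | None = None) -> str:
        concepts.append(Concept(key, label or key, name))
        return key

    target = add("T", "target region")
    table.set(target, Marker.parse("SANOPS:4"))
    root = add("ROOT", "unrelated root")
    focus = add("F", "anatomic focus")

    region_attr = None
    if spec.planted_class == 1:
        region_attr = add("RA", "region attribute")
        table.set(region_attr, Marker.parse("SANOPS:4"))
        edges.append(Edge(focus, root, uniform))
    elif spec.planted_class == 2:
        chain = [focus]
        for i in range(rng.randint(0, 2)):
            chain.append(add(f"C{i}", f"chain {i}"))
        chain.append(target)
        for a, b_ in zip(chain, chain[1:]):
            edges.append(Edge(a, b_, uniform))
    elif spec.planted_class == 3:
        edges.append(Edge(focus, target, uniform))
        branch = add("B", "bypass branch")
        edges.append(Edge(focus, branch, rng.choice(rootward)))
        edges.append(Edge(branch, root, rng.choice(rootward)))
    elif spec.planted_class == 4:
        part = add("P", "regional part")
        edges.append(Edge(focus, part, RelationType.HAS_PART))
        edges.append(Edge(part, target, uniform))
        edges.append(Edge(focus, root, uniform))
    else:  # class 5: no route from focus to target at all
        edges.append(Edge(focus, root, uniform))

    # decoration: extra concepts point INTO the motif (never out of it),
    # so they cannot create new walks from the focus
    motif_ids = [c.id for c in concepts]
    n_extra = max(0, spec.n_concepts - len(concepts))
    for i in range(n_extra):
        extra = add(f"X{i}", f"decoration {i}")
        sink = rng.choice(motif_ids)
        edges.append(Edge(extra, sink, rng.choice(list(spec.palette))))

    graph = TerminologyGraph(name, concepts, edges)
    mapping = ExamAnatomicMapping(
        exam_code=f"GEN-{spec.seed}",
        exam_name=f"generated exam (class {spec.planted_class})",
        terminology=name,
        region_attribute=(region_attr,) if region_attr else (),
        focus_attribute=(focus,),
        target_regions=("4",),
    )
    return graph, mapping, table


def random_class_sample(
    seed: int,
    n: int,
    class_probabilities: dict[str, "list[float]"],
) -> dict[str, list[int]]:
    """Reproducible ordinal samples on {1..5}, one list per terminology."""
    if n < 1:
        raise SpecError("n must be >= 1")
    rng = random.Random(seed)
    sample: dict[str, list[int]] = {}
    for terminology in sorted(class_probabilities):
        probs = list(class_probabilities[terminology])
        if len(probs) != 5 or any(p < 0 for p in probs):
            raise SpecError(
                f"{terminology}: need 5 non-negative class probabilities"
            )
        if abs(sum(probs) - 1.0) > 1e-9:
            raise SpecError(f"{terminology}: probabilities must sum to 1")
        sample[terminology] = rng.choices(
            population=[1, 2, 3, 4, 5], weights=probs, k=n
        )
    return sample
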