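"""The 17-region body model, its adjacency relation, and alert rules.

Regions 1-5 form the midline chain head / neck / chest / abdomen / pelvis.
Each extremity is split into proximal (a), mid (b) and distal (c) thirds,
with boundaries at the midshafts of the long bones, so each extremity
region roughly corresponds to a large joint plus adjacent shaft.  Codes:
6 = left upper, 7 = right upper, 8 = left lower, 9 = right lower.

Alert semantics for a pair of exams: SAME when the exam codes are equal;
SIMILAR when different codes share at least one assigned region; PROXIMATE
when their region sets are disjoint but some pair of assigned regions is
adjacent; NONE otherwise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from .errors import GraphValidationError, SanopsError

__all__ = [
    "SanopsRegion",
    "AdjacencyTable",
    "RegionAssignment",
    "AlertClass",
    "REGION_CODES",
    "EXTREMITY_LIMBS",
    "default_regions",
    "default_adjacency",
    "region_by_code",
    "alert_relation",
]


@dataclass(frozen=True, order=True)
class SanopsRegion:
    """One of the 17 major body regions."""

    code: str
    label: str


# (code, label) in code order; extremity labels follow the proximal/mid/
# distal x left/right x upper/lower scheme.
_REGION_TABLE: tuple[tuple[str, str], ...] = (
    ("1", "head"),
    ("2", "neck"),
    ("3", "chest"),
    ("4", "abdomen"),
    ("5", "pelvis"),
    ("6a", "proximal left upper extremity (LUE)"),
    ("6b", "mid left upper extremity (LUE)"),
    ("6c", "distal left upper extremity (LUE)"),
    ("7a", "proximal right upper extremity (RUE)"),
    ("7b", "mid right upper extremity (RUE)"),
    ("7c", "distal right upper extremity (RUE)"),
    ("8a", "proximal left lower extremity (LLE)"),
    ("8b", "mid left lower extremity (LLE)"),
    ("8c", "distal left lower extremity (LLE)"),
    ("9a", "proximal right lower extremity (RLE)"),
    ("9b", "mid right lower extremity (RLE)"),
    ("9c", "distal right lower extremity (RLE)"),
)

REGION_CODES: tuple[str, ...] = tuple(code for code, _ in _REGION_TABLE)

#: Limb id -> the three region codes of that limb, proximal to distal.
EXTREMITY_LIMBS: dict[str, tuple[str, str, str]] = {
    "LUE": ("6a", "6b", "6c"),
    "RUE": ("7a", "7b", "7c"),
    "LLE": ("8a", "8b", "8c"),
    "RLE": ("9a", "9b", "9c"),
}

_REGIONS: dict[str, SanopsRegion] = {
    code: SanopsRegion(code, label) for code, label in _REGION_TABLE
}


def default_regions() -> list[SanopsRegion]:
    """The 17 regions in code order."""
    return [_REGIONS[c] for c in REGION_CODES]


def region_by_code(code: str) -> SanopsRegion:
    try:
        return _REGIONS[code]
    except KeyError:
        raise SanopsError(f"unknown region code {code!r}") from None


class AdjacencyTable:
    """Symmetric, irreflexive adjacency over region codes."""

    def __init__(self, pairs: set[frozenset[str]] | None = None) -> None:
        self._pairs: set[frozenset[str]] = set()
        for pair in pairs or ():
            a, b = sorted(pair)
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        region_by_code(a)
        region_by_code(b)
        if a == b:
            raise SanopsError(f"region {a!r} cannot be adjacent to itself")
        self._pairs.add(frozenset((a, b)))

    def adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._pairs

    def neighbors(self, code: str) -> set[str]:
        region_by_code(code)
        out: set[str] = set()
        for pair in self._pairs:
            if code in pair:
                out |= pair - {code}
        return out

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AdjacencyTable":
        """Read an override table: CSV with columns code_a, code_b."""
        table = cls()
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                table.add(row["code_a"].strip(), row["code_b"].strip())
        return table

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["code_a", "code_b"])
            writer.writerows(self.pairs())


def default_adjacency() -> AdjacencyTable:
    """The built-in adjacency table.

    Midline chain 1-2-3-4-5; chest adjoins each proximal upper-extremity
    region and pelvis each proximal lower-extremity region; within a limb,
    proximal-mid and mid-distal adjoin.  No cross-limb adjacency, and
    proximal/distal of the same limb do NOT adjoin (a prior foot CT must
    not alert on a new hip CT order).
    """
    table = AdjacencyTable()
    for a, b in (("1", "2"), ("2", "3"), ("3", "4"), ("4", "5")):
        table.add(a, b)
    table.add("3", "6a")
    table.add("3", "7a")
    table.add("5", "8a")
    table.add("5", "9a")
    for prox, mid, dist in EXTREMITY_LIMBS.values():
        table.add(prox, mid)
        table.add(mid, dist)
    return table


@dataclass(frozen=True)
class RegionAssignment:
    """An exam code's set of assigned body regions.

    Exams spanning more than one major region carry multiple codes, e.g.
    an abdomen-and-pelvis exam and a lumbar spine exam are both assigned
    {4, 5}.
    """

    exam_code: str
    regions: frozenset[str]

    def __post_init__(self) -> None:
        for code in self.regions:
            region_by_code(code)

    def validated(self) -> "RegionAssignment":
        if not self.regions:
            raise GraphValidationError(
                f"exam {self.exam_code!r} has an empty region set"
            )
        return self


class AlertClass(Enum):
    """Alert verdict, in decreasing precedence."""

    SAME = "same"
    SIMILAR = "similar"
    PROXIMATE = "proximate"
    NONE = "none"

    @property
    def precedence(self) -> int:
        return {"same": 3, "similar": 2, "proximate": 1, "none": 0}[self.value]

    @property
    def fired(self) -> bool:
        return self in (AlertClass.SAME, AlertClass.SIMILAR, AlertClass.PROXIMATE)


def alert_relation(
    a: RegionAssignment,
    b: RegionAssignment,
    same_code: bool,
    table: AdjacencyTable,
) -> AlertClass:
    """Classify the relation between two region assignments.

    SAME wins outright on equal exam codes.  Otherwise SIMILAR when the
    region sets intersect, PROXIMATE when they are disjoint but adjacent
    under ``table``, NONE otherwise; symmetric in (a, b).
    """
    if same_code:
        return AlertClass.SAME
    a.validated()
    b.validated()
    if a.regions & b.regions:
        return AlertClass.SIMILAR
    for r in a.regions:
        for s in b.regions:
            if table.adjacent(r, s):
                return AlertClass.PROXIMATE
    return AlertClass.NONE
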