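"""Order-time alert decisions for exam pairs and exam histories.

A terminology backend bundles a terminology graph, the exam-code mappings
into it, and the concept-to-region correspondence table.  ``max_class``
sets how much graph machinery the deployment is willing to run: 1 uses
only directly attributed region markers (the terminology "as is"), while
2-4 progressively admit regions recovered through lookup tables and walk
algorithms graded by the utility classifier.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

from .errors import ClassificationError, LookupError_
from .sanops_model import (
    AdjacencyTable,
    AlertClass,
    RegionAssignment,
    alert_relation,
)
from .terminology_graph import DEFAULT_MAX_PATH_LENGTH, TerminologyGraph
from .utility_classifier import (
    CorrespondenceTable,
    ExamAnatomicMapping,
    classify,
)

__all__ = [
    "ExamRecord",
    "TerminologyBackend",
    "AlertDecision",
    "resolve_regions",
    "decide_alert",
    "run_scenarios",
    "alert_history",
    "load_exam_history",
]


@dataclass(frozen=True)
class ExamRecord:
    """One exam event in a patient's history."""

    patient_id: str
    site_id: str
    exam_code: str
    timestamp: datetime

    def __post_init__(self) -> None:
        if not self.exam_code:
            raise ValueError("exam_code must be non-empty")
        if isinstance(self.timestamp, str):
            object.__setattr__(
                self, "timestamp", datetime.fromisoformat(self.timestamp)
            )


@dataclass
class TerminologyBackend:
    """Everything needed to resolve exam codes to body regions."""

    name: str
    graph: TerminologyGraph
    mappings: dict[str, ExamAnatomicMapping]
    correspondence: CorrespondenceTable

    def mapping(self, exam_code: str) -> ExamAnatomicMapping:
        try:
            return self.mappings[exam_code]
        except KeyError:
            raise LookupError_(
                f"exam code {exam_code!r} has no mapping in backend "
                f"{self.name!r}"
            ) from None

    def validate(self) -> None:
        self.graph.validate()
        self.correspondence.validate_against(self.graph)
        for mapping in self.mappings.values():
            for cid in mapping.attributes:
                self.graph.concept(cid)


@dataclass(frozen=True)
class AlertDecision:
    """Verdict for one (current, prior) exam pair, with provenance."""

    alert: AlertClass
    current: ExamRecord
    prior: ExamRecord
    regions_current: frozenset[str]
    regions_prior: frozenset[str]
    max_class_used: int
    terminology: str


def resolve_regions(
    backend: TerminologyBackend,
    exam_code: str,
    max_class: int = 1,
    max_length: int = DEFAULT_MAX_PATH_LENGTH,
) -> frozenset[str]:
    """Region codes recoverable for ``exam_code`` at utility <= max_class.

    Class-1 markers on the exam's attributes contribute their regions
    directly; for ``max_class`` >= 2, each region named by the exam whose
    per-region utility class falls in [2, max_class] is added as well.
    Returns the empty set when nothing resolves (never an error at
    decision time).
    """
    if not 1 <= max_class <= 5:
        raise ValueError("max_class must be in 1..5")
    mapping = backend.mapping(exam_code)

    regions: set[str] = set()
    for cid in mapping.attributes:
        marker = backend.correspondence.marker(cid)
        if marker is not None:
            regions |= marker.regions

    if max_class >= 2 and mapping.target_regions:
        try:
            result = classify(
                backend.graph, mapping, backend.correspondence, max_length
            )
        except ClassificationError:
            result = None
        if result is not None:
            for rr in result.per_region:
                if rr.value is not None and 2 <= rr.value <= min(max_class, 4):
                    regions.add(rr.region)
    return frozenset(regions)


def decide_alert(
    backend: TerminologyBackend,
    current: ExamRecord,
    prior: ExamRecord,
    max_class: int = 1,
    table: AdjacencyTable | None = None,
) -> AlertDecision:
    """Decide the alert relation between a current order and one prior."""
    from .sanops_model import default_adjacency

    table = table if table is not None else default_adjacency()
    same_code = current.exam_code == prior.exam_code
    regions_cur = resolve_regions(backend, current.exam_code, max_class)
    regions_pri = resolve_regions(backend, prior.exam_code, max_class)

    if same_code:
        alert = AlertClass.SAME
    elif not regions_cur or not regions_pri:
        alert = AlertClass.NONE
    else:
        alert = alert_relation(
            RegionAssignment(current.exam_code, regions_cur),
            RegionAssignment(prior.exam_code, regions_pri),
            same_code=False,
            table=table,
        )
    return AlertDecision(
        alert=alert,
        current=current,
        prior=prior,
        regions_current=regions_cur,
        regions_prior=regions_pri,
        max_class_used=max_class,
        terminology=backend.name,
    )


def alert_history(
    backend: TerminologyBackend,
    current: ExamRecord,
    priors: list[ExamRecord],
    max_class: int = 1,
    table: AdjacencyTable | None = None,
    lookback: "datetime | None" = None,
) -> list[AlertDecision]:
    """One decision per prior, ranked SAME > SIMILAR > PROXIMATE > NONE,
    ties broken by most recent prior first.

    ``lookback`` optionally drops priors before the given instant; the
    default keeps the whole history.
    """
    considered = [
        p for p in priors if lookback is None or p.timestamp >= lookback
    ]
    decisions = [
        decide_alert(backend, current, prior, max_class, table)
        for prior in considered
    ]
    decisions.sort(
        key=lambda d: (-d.alert.precedence, -d.prior.timestamp.timestamp())
    )
    return decisions


def run_scenarios(
    backends: dict[str, TerminologyBackend],
    scenarios: list,
    max_class: int = 1,
    table: AdjacencyTable | None = None,
) -> dict[int, dict[str, AlertDecision]]:
    """Evaluate every scenario against every backend.

    ``scenarios`` rows need ``number``, ``prior_code`` and
    ``current_code`` attributes.  Raises a lookup error naming the
    backend and code when an exam is unmapped.  A cell "fires" when its
    decision is SIMILAR or PROXIMATE.
    """
    matrix: dict[int, dict[str, AlertDecision]] = {}
    epoch_prior = datetime(2015, 12, 1, 8, 0)
    epoch_cur = datetime(2016, 1, 1, 8, 0)
    for row in scenarios:
        cells: dict[str, AlertDecision] = {}
        for name, backend in backends.items():
            for code in (row.prior_code, row.current_code):
                backend.mapping(code)  # raises naming backend + code
            prior = ExamRecord("pt-1", "site-a", row.prior_code, epoch_prior)
            current = ExamRecord("pt-1", "site-b", row.current_code, epoch_cur)
            cells[name] = decide_alert(backend, current, prior, max_class, table)
        matrix[row.number] = cells
    return matrix


def load_exam_history(path: str | Path) -> list[ExamRecord]:
    """Read (patient_id, site_id, exam_code, timestamp) CSV rows."""
    records: list[ExamRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            records.append(
                ExamRecord(
                    patient_id=row["patient_id"],
                    site_id=row["site_id"],
                    exam_code=row["exam_code"],
                    timestamp=datetime.fromisoformat(row["timestamp"]),
                )
            )
    return records
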