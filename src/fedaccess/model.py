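"""Domain types shared by broker, node client, simulator and analytics."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional

from .states import LEGAL_EDGES, QueryState, SENTINEL_NEW

__all__ = [
    "COVER_LETTER_SEGMENTS",
    "CoverLetter",
    "Requester",
    "RequestManifest",
    "QueryInstance",
    "ProvenanceEvent",
    "NodeQueryRecord",
    "KPICategory",
    "EmptyHistory",
    "InvalidManifest",
    "make_query_id",
    "split_query_id",
    "categorize",
    "state_at",
]

#: Ordered cover-letter segment names, mirroring how a data request is
#: presented to the deciding clinician: why the data is wanted, what will
#: be answered, what is included, who processes it, and the standing
#: ethics/privacy commitments.
COVER_LETTER_SEGMENTS = (
    "rationale",
    "research_questions_and_outcomes",
    "inclusion_criteria_and_variables",
    "processors_and_purpose",
    "ethics_and_privacy_commitments",
)


class InvalidManifest(Exception):
    """Raised when a request manifest violates its invariants."""


class EmptyHistory(Exception):
    """Raised when a record has no provenance events to classify."""


@dataclass(frozen=True)
class Requester:
    name: str
    affiliation: str
    email: str


@dataclass(frozen=True)
class CoverLetter:
    """Human-readable request description, segmented for reviewability."""

    rationale: str = ""
    research_questions_and_outcomes: str = ""
    inclusion_criteria_and_variables: str = ""
    processors_and_purpose: str = ""
    ethics_and_privacy_commitments: str = ""

    def empty_segments(self) -> list[str]:
        """Names of segments left blank (flagged, not fatal)."""
        return [s for s in COVER_LETTER_SEGMENTS if not getattr(self, s).strip()]


@dataclass
class RequestManifest:
    """A data request as published by the broker.

    ``query_type`` is ``"single"`` for one-off requests and ``"series"``
    for periodic requests that emit a new query instance every
    ``series_interval``.
    """

    request_id: str
    query_type: str  # "single" | "series"
    syntax_language: str  # "sql" | "r"
    syntax_body: str
    requester: Requester
    reference_date: datetime
    execution_date: datetime
    cover_letter: CoverLetter
    target_nodes: frozenset[str]
    series_interval: Optional[timedelta] = None
    series_count: Optional[int] = None  # emissions; None = open-ended
    retroactive: bool = False  # execution_date may precede publication

    def validate(self, publication_time: Optional[datetime] = None) -> list[str]:
        """Return a list of violation messages (empty means valid)."""
        issues: list[str] = []
        if self.query_type not in ("single", "series"):
            issues.append(f"unknown query_type {self.query_type!r}")
        if (self.series_interval is not None) != (self.query_type == "series"):
            issues.append("series_interval must be present iff query_type is series")
        if self.series_interval is not None and self.series_interval <= timedelta(0):
            issues.append("series_interval must be positive")
        if self.series_count is not None:
            if self.query_type != "series":
                issues.append("series_count only applies to series requests")
            elif self.series_count < 1:
                issues.append("series_count must be >= 1")
        if not self.target_nodes:
            issues.append("no target nodes")
        if self.syntax_language not in ("sql", "r"):
            issues.append(f"unknown syntax_language {self.syntax_language!r}")
        if (
            publication_time is not None
            and self.execution_date < publication_time
            and not self.retroactive
        ):
            issues.append(
                "execution_date precedes publication and manifest is not "
                "marked retroactive"
            )
        return issues

    def check(self, publication_time: Optional[datetime] = None) -> None:
        issues = self.validate(publication_time)
        if issues:
            raise InvalidManifest("; ".join(issues))


def make_query_id(request_id: str, sequence_no: int) -> str:
    """Canonical query-instance id: ``<request_id>#<sequence_no>``."""
    return f"{request_id}#{sequence_no}"


def split_query_id(query_id: str) -> tuple[str, int]:
    """Inverse of :func:`make_query_id`; bare ids parse as sequence 0."""
    if "#" in query_id:
        req, _, seq = query_id.rpartition("#")
        try:
            return req, int(seq)
        except ValueError:
            pass
    return query_id, 0


@dataclass(frozen=True)
class QueryInstance:
    """One emission of a request: the unit delivered to and decided by nodes."""

    query_id: str
    request_id: str
    sequence_no: int
    due_time: datetime

    def __post_init__(self) -> None:
        if self.sequence_no < 0:
            raise ValueError("sequence_no must be >= 0")


@dataclass(frozen=True)
class ProvenanceEvent:
    """One append-only state-change record; the unit of the event log.

    ``from_state`` is ``None`` for the initial delivery transition
    (serialized as the token ``NEW``).  Timestamps are UTC at second
    resolution; ties are broken by insertion order.
    """

    timestamp: datetime
    node_id: str
    query_id: str
    from_state: Optional[QueryState]
    to_state: QueryState
    actor: str  # "user" | "system" | "auto-rule"

    def __post_init__(self) -> None:
        ts = self.timestamp
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        else:
            ts = ts.astimezone(timezone.utc)
        ts = ts.replace(microsecond=0)
        object.__setattr__(self, "timestamp", ts)
        if not self.is_legal_edge(self.from_state, self.to_state):
            raise ValueError(
                f"illegal provenance edge {self.from_token} -> {self.to_state}"
            )

    @staticmethod
    def is_legal_edge(
        from_state: Optional[QueryState], to_state: QueryState
    ) -> bool:
        if from_state is None:
            return to_state is QueryState.RETRIEVED
        return (from_state, to_state) in LEGAL_EDGES

    @property
    def from_token(self) -> str:
        return SENTINEL_NEW if self.from_state is None else self.from_state.value


@dataclass
class NodeQueryRecord:
    """One query instance at one node: current state plus full history."""

    node_id: str
    query: QueryInstance
    state: QueryState
    history: list[ProvenanceEvent] = field(default_factory=list)
    result_ref: Optional[str] = None
    failure_reason: Optional[str] = None
    review: bool = False

    def append(self, event: ProvenanceEvent) -> None:
        if self.history and event.timestamp < self.history[-1].timestamp:
            raise ValueError("history timestamps must be non-decreasing")
        self.history.append(event)
        self.state = event.to_state

    def replayed_state(self) -> QueryState:
        """State reconstructed from history; must equal ``state``."""
        if not self.history:
            raise EmptyHistory(self.query.query_id)
        return self.history[-1].to_state

    @property
    def retrieved_at(self) -> datetime:
        if not self.history:
            raise EmptyHistory(self.query.query_id)
        return self.history[0].timestamp

    def terminal_time(self) -> Optional[datetime]:
        from .states import TERMINAL_STATES

        for ev in self.history:
            if ev.to_state in TERMINAL_STATES:
                return ev.timestamp
        return None


class KPICategory(str, enum.Enum):
    """Mutually exclusive, exhaustive classification at a cutoff date."""

    COMPLETED = "COMPLETED"
    FAILED = "FAILED"
    REJECTED = "REJECTED"
    #: still RETRIEVED or SEEN at cutoff — never acted on
    UNANSWERED = "UNANSWERED"
    #: executed into review, result never released nor withheld
    REVIEW_UNANSWERED = "REVIEW_UNANSWERED"
    #: accepted or mid-execution at cutoff; kept separate so the six
    #: categories always partition the record set
    PENDING_OTHER = "PENDING_OTHER"

    def __str__(self) -> str:
        return self.value


_STATE_TO_CATEGORY = {
    QueryState.COMPLETED: KPICategory.COMPLETED,
    QueryState.FAILED: KPICategory.FAILED,
    QueryState.REJECTED: KPICategory.REJECTED,
    QueryState.RETRIEVED: KPICategory.UNANSWERED,
    QueryState.SEEN: KPICategory.UNANSWERED,
    QueryState.INTERACTION: KPICategory.REVIEW_UNANSWERED,
    QueryState.ACCEPTED: KPICategory.PENDING_OTHER,
    QueryState.PROCESSING: KPICategory.PENDING_OTHER,
}


def state_at(record: NodeQueryRecord, cutoff: datetime) -> QueryState:
    """State effective at ``cutoff`` (events after cutoff ignored)."""
    if not record.history:
        raise EmptyHistory(record.query.query_id)
    if cutoff < record.history[0].timestamp:
        raise ValueError("cutoff precedes first provenance event")
    state = record.history[0].to_state
    for ev in record.history[1:]:
        if ev.timestamp > cutoff:
            break
        state = ev.to_state
    return state


def categorize(record: NodeQueryRecord, cutoff: datetime) -> KPICategory:
    """Classify ``record`` into its KPI category as of ``cutoff``."""
    return _STATE_TO_CATEGORY[state_at(record, cutoff)]
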