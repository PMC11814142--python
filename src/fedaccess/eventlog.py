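"""Provenance event-log serialization (CSV and JSONL) and reconstruction.

The native log dialect is a flat table with header
``timestamp,node_id,query_id,from_state,to_state,actor`` and ISO-8601
UTC timestamps at second resolution.  ``from_state`` uses the token
``NEW`` for the initial delivery edge.
"""

from __future__ import annotations

import csv
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .model import NodeQueryRecord, ProvenanceEvent, QueryInstance, split_query_id
from .states import QueryState, SENTINEL_NEW

__all__ = [
    "FIELDNAMES",
    "ParseError",
    "write_csv",
    "write_jsonl",
    "read_csv",
    "read_jsonl",
    "sort_events",
    "records_from_events",
]

FIELDNAMES = ("timestamp", "node_id", "query_id", "from_state", "to_state", "actor")


class ParseError(Exception):
    """Raised on malformed log rows or illegal transition histories."""


def _format_ts(ts: datetime) -> str:
    return ts.astimezone(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def _parse_ts(token: str) -> datetime:
    token = token.strip()
    if token.endswith("Z"):
        token = token[:-1] + "+00:00"
    ts = datetime.fromisoformat(token)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def _event_row(ev: ProvenanceEvent) -> dict[str, str]:
    return {
        "timestamp": _format_ts(ev.timestamp),
        "node_id": ev.node_id,
        "query_id": ev.query_id,
        "from_state": ev.from_token,
        "to_state": ev.to_state.value,
        "actor": ev.actor,
    }


def _row_event(row: dict[str, str], lineno: int) -> ProvenanceEvent:
    try:
        from_tok = row["from_state"]
        from_state = None if from_tok == SENTINEL_NEW else QueryState(from_tok)
        return ProvenanceEvent(
            timestamp=_parse_ts(row["timestamp"]),
            node_id=row["node_id"],
            query_id=row["query_id"],
            from_state=from_state,
            to_state=QueryState(row["to_state"]),
            actor=row["actor"],
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def sort_events(events: Iterable[ProvenanceEvent]) -> list[ProvenanceEvent]:
    """Timestamp order, stable in insertion order for ties."""
    return sorted(events, key=lambda ev: ev.timestamp)


def write_csv(events: Iterable[ProvenanceEvent], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=FIELDNAMES)
        writer.writeheader()
        for ev in sort_events(events):
            writer.writerow(_event_row(ev))


def read_csv(path: str | Path) -> list[ProvenanceEvent]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != FIELDNAMES:
            raise ParseError(f"unexpected header: {reader.fieldnames}")
        return [_row_event(row, i) for i, row in enumerate(reader, start=2)]


def write_jsonl(events: Iterable[ProvenanceEvent], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ev in sort_events(events):
            fh.write(json.dumps(_event_row(ev)) + "\n")


def read_jsonl(path: str | Path) -> list[ProvenanceEvent]:
    events = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                row = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"line {i}: {exc}") from exc
            events.append(_row_event(row, i))
    return events


def records_from_events(
    events: Sequence[ProvenanceEvent],
    strict: bool = True,
) -> tuple[list[NodeQueryRecord], list[str]]:
    """Reconstruct per-(node, query) histories from a flat event stream.

    Returns ``(records, quarantined)`` where ``quarantined`` lists the
    ``node_id/query_id`` keys whose histories violate the transition
    graph.  In strict mode the first violation raises :class:`ParseError`
    naming the query instead.
    """
    by_key: dict[tuple[str, str], list[ProvenanceEvent]] = {}
    for ev in sort_events(events):
        by_key.setdefault((ev.node_id, ev.query_id), []).append(ev)

    records: list[NodeQueryRecord] = []
    quarantined: list[str] = []
    for (node_id, query_id), history in by_key.items():
        problem: Optional[str] = None
        if history[0].from_state is not None:
            problem = f"history does not start at {SENTINEL_NEW}"
        else:
            state = history[0].to_state
            for ev in history[1:]:
                if ev.from_state != state or not ProvenanceEvent.is_legal_edge(
                    ev.from_state, ev.to_state
                ):
                    problem = (
                        f"illegal transition {ev.from_token} -> {ev.to_state} "
                        f"(state was {state})"
                    )
                    break
                state = ev.to_state
        if problem is not None:
            if strict:
                raise ParseError(f"query {query_id} at node {node_id}: {problem}")
            quarantined.append(f"{node_id}/{query_id}")
            continue
        request_id, seq = split_query_id(query_id)
        record = NodeQueryRecord(
            node_id=node_id,
            query=QueryInstance(
                query_id=query_id,
                request_id=request_id,
                sequence_no=seq,
                due_time=history[0].timestamp,
            ),
            state=history[-1].to_state,
            history=list(history),
        )
        records.append(record)
    return records, quarantined
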