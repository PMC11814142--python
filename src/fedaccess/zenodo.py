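"""Adapter for externally deposited operational log datasets.

Public deposits of broker logs do not use this package's native event
dialect, so ``load_event_log(..., dialect="zenodo")`` routes through
this plugin.  The concrete deposit schema could not be inspected when
the adapter was written (no network access to the archive); the default
column mapping below is therefore an *assumed* layout and is fully
overridable via ``columns=...`` / ``layout=...`` once the real files are
at hand.  Two layouts are supported:

``wide``
    one row per (query, node) with one timestamp column per state
    reached, e.g. ``query,node,retrieved,seen,accepted,processing,
    completed,failed,rejected,interaction`` (empty = never reached).

``long``
    one row per state change: ``timestamp,node,query,status``.

Both are normalized into the native provenance-event stream; transition
legality is then checked by the regular loader.
"""

from __future__ import annotations

import csv
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

from .eventlog import ParseError
from .model import ProvenanceEvent
from .states import QueryState

__all__ = ["read_deposit_events", "WIDE_STATE_COLUMNS"]

#: assumed wide-layout state columns, in canonical workflow order
WIDE_STATE_COLUMNS = {
    "retrieved": QueryState.RETRIEVED,
    "seen": QueryState.SEEN,
    "accepted": QueryState.ACCEPTED,
    "processing": QueryState.PROCESSING,
    "interaction": QueryState.INTERACTION,
    "completed": QueryState.COMPLETED,
    "failed": QueryState.FAILED,
    "rejected": QueryState.REJECTED,
}

_CANONICAL_RANK = {state: i for i, state in enumerate(WIDE_STATE_COLUMNS.values())}

_DEFAULT_KEYS = {"query_id": "query", "node_id": "node",
                 "timestamp": "timestamp", "status": "status"}


def _parse_ts(token: str) -> datetime:
    token = token.strip()
    if token.endswith("Z"):
        token = token[:-1] + "+00:00"
    ts = datetime.fromisoformat(token)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts.astimezone(timezone.utc)


def read_deposit_events(
    path: Union[str, Path],
    layout: str = "wide",
    columns: Optional[dict[str, str]] = None,
    actor: str = "user",
) -> list[ProvenanceEvent]:
    """Normalize a deposited log table into provenance events.

    ``columns`` overrides the assumed column names: keys are the logical
    names (``query_id``, ``node_id``, ``timestamp``, ``status``, and for
    the wide layout the state names of :data:`WIDE_STATE_COLUMNS`),
    values the column names found in the file.
    """
    colmap = dict(_DEFAULT_KEYS)
    colmap.update({k: k for k in WIDE_STATE_COLUMNS})
    if columns:
        colmap.update(columns)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if layout == "wide":
        return _from_wide(rows, colmap, actor)
    if layout == "long":
        return _from_long(rows, colmap, actor)
    raise ParseError(f"unknown deposit layout {layout!r}")


def _chain(query_id: str, node_id: str,
           stamped: list[tuple[datetime, QueryState]],
           actor: str) -> list[ProvenanceEvent]:
    stamped.sort(key=lambda sv: (sv[0], _CANONICAL_RANK[sv[1]]))
    if not stamped or stamped[0][1] is not QueryState.RETRIEVED:
        raise ParseError(f"query {query_id} at node {node_id}: no retrieval record")
    events = []
    prev: Optional[QueryState] = None
    for ts, state in stamped:
        if not ProvenanceEvent.is_legal_edge(prev, state):
            raise ParseError(
                f"query {query_id} at node {node_id}: cannot chain "
                f"{prev} -> {state.value}"
            )
        events.append(
            ProvenanceEvent(timestamp=ts, node_id=node_id, query_id=query_id,
                            from_state=prev, to_state=state, actor=actor)
        )
        prev = state
    return events


def _from_wide(rows, colmap, actor) -> list[ProvenanceEvent]:
    events: list[ProvenanceEvent] = []
    for i, row in enumerate(rows, start=2):
        try:
            query_id = row[colmap["query_id"]]
            node_id = row[colmap["node_id"]]
        except KeyError as exc:
            raise ParseError(f"line {i}: missing column {exc}") from exc
        stamped = []
        for name, state in WIDE_STATE_COLUMNS.items():
            token = row.get(colmap[name], "") or ""
            if token.strip():
                stamped.append((_parse_ts(token), state))
        events.extend(_chain(query_id, node_id, stamped, actor))
    return events


def _from_long(rows, colmap, actor) -> list[ProvenanceEvent]:
    per_query: dict[tuple[str, str], list[tuple[datetime, QueryState]]] = {}
    for i, row in enumerate(rows, start=2):
        try:
            key = (row[colmap["node_id"]], row[colmap["query_id"]])
            status = row[colmap["status"]].strip().lower()
            ts = _parse_ts(row[colmap["timestamp"]])
        except KeyError as exc:
            raise ParseError(f"line {i}: missing column {exc}") from exc
        if status not in WIDE_STATE_COLUMNS:
            raise ParseError(f"line {i}: unknown status {status!r}")
        per_query.setdefault(key, []).append((ts, WIDE_STATE_COLUMNS[status]))
    events: list[ProvenanceEvent] = []
    for (node_id, query_id), stamped in per_query.items():
        events.extend(_chain(query_id, node_id, stamped, actor))
    return events
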