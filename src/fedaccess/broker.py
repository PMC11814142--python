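"""Central broker: publishes requests, answers polls, logs provenance.

The broker is content-agnostic — it never interprets query syntax.  It
holds the registry of nodes (each secured by an individual API key), the
published manifests, per-(node, query) delivery state, uploaded result
payloads, and the append-only provenance event log that the analytics
layer consumes.  Series requests emit new query instances lazily as the
scheduler is ticked past their due times.
"""

from __future__ import annotations

import csv
import io
import logging
import secrets
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import eventlog
from .clock import SystemClock
from .model import (
    InvalidManifest,
    NodeQueryRecord,
    ProvenanceEvent,
    QueryInstance,
    RequestManifest,
    make_query_id,
)
from .states import (
    IllegalTransition,
    LifecycleEvent,
    QueryState,
    next_state,
)

__all__ = [
    "Broker",
    "NodeRegistration",
    "RequestStatusBoard",
    "AuthFailure",
    "DuplicateNode",
    "UnknownNode",
    "UnknownQuery",
    "UnknownTargetNode",
    "MalformedPayload",
    "NoResults",
]

log = logging.getLogger(__name__)


class AuthFailure(Exception):
    """API key missing, wrong, or node deactivated."""


class DuplicateNode(Exception):
    pass


class UnknownNode(Exception):
    pass


class UnknownQuery(Exception):
    pass


class UnknownTargetNode(Exception):
    pass


class MalformedPayload(Exception):
    pass


class NoResults(Exception):
    pass


@dataclass
class NodeRegistration:
    node_id: str
    api_key: str
    joined: datetime
    active: bool = True


@dataclass
class RequestStatusBoard:
    """Per-node view of one request: latest state and result availability."""

    request_id: str
    states: dict[str, QueryState] = field(default_factory=dict)
    has_result: dict[str, bool] = field(default_factory=dict)


@dataclass
class _Delivery:
    """Broker-side record of one query instance at one node."""

    node_id: str
    query: QueryInstance
    state: QueryState
    review: bool = False


def _validate_csv_payload(payload: str) -> None:
    rows = list(csv.reader(io.StringIO(payload)))
    if not rows or not rows[0] or all(not c.strip() for c in rows[0]):
        raise MalformedPayload("payload has no header row")
    width = len(rows[0])
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise MalformedPayload(f"row {i} has {len(row)} fields, header has {width}")


class Broker:
    """In-process broker service (the wire protocol is not normative)."""

    def __init__(self, clock=None):
        self.clock = clock if clock is not None else SystemClock()
        self._nodes: dict[str, NodeRegistration] = {}
        self._manifests: dict[str, RequestManifest] = {}
        self._next_emission: dict[str, int] = {}  # series scheduling cursor
        self._queues: dict[str, list[QueryInstance]] = {}
        self._deliveries: dict[tuple[str, str], _Delivery] = {}
        self._events: list[ProvenanceEvent] = []
        self._payloads: dict[tuple[str, str], str] = {}

    # -- registry ---------------------------------------------------------

    def register_node(
        self, node_id: str, joined: Optional[datetime] = None
    ) -> NodeRegistration:
        if node_id in self._nodes:
            raise DuplicateNode(node_id)
        reg = NodeRegistration(
            node_id=node_id,
            api_key=secrets.token_hex(16),
            joined=joined if joined is not None else self.clock.now(),
        )
        self._nodes[node_id] = reg
        self._queues[node_id] = []
        return reg

    def deactivate_node(self, node_id: str) -> None:
        try:
            self._nodes[node_id].active = False
        except KeyError:
            raise UnknownNode(node_id) from None

    def active_nodes(self) -> list[str]:
        return sorted(n for n, r in self._nodes.items() if r.active)

    def _auth(self, node_id: str, api_key: str) -> NodeRegistration:
        reg = self._nodes.get(node_id)
        if reg is None:
            raise UnknownNode(node_id)
        if not reg.active or not secrets.compare_digest(reg.api_key, api_key):
            raise AuthFailure(node_id)
        return reg

    # -- publication and scheduling ---------------------------------------

    def publish_request(
        self, manifest: RequestManifest, now: Optional[datetime] = None
    ) -> list[QueryInstance]:
        """Validate and publish; returns the first-emission instances.

        One query instance is delivered per target node per emission.
        Later emissions of a series are generated lazily by :meth:`tick`.
        """
        now = now if now is not None else self.clock.now()
        issues = manifest.validate(publication_time=now)
        if issues:
            raise InvalidManifest("; ".join(issues))
        if manifest.request_id in self._manifests:
            raise InvalidManifest(f"duplicate request id {manifest.request_id}")
        unknown = manifest.target_nodes - self._nodes.keys()
        if unknown:
            raise UnknownTargetNode(", ".join(sorted(unknown)))
        self._manifests[manifest.request_id] = manifest
        log.info(
            "published request_id=%s type=%s targets=%d",
            manifest.request_id,
            manifest.query_type,
            len(manifest.target_nodes),
        )
        instances = self._emit(manifest, sequence_no=0, due=manifest.execution_date)
        if manifest.query_type == "series":
            self._next_emission[manifest.request_id] = 1
        return instances

    def _emit(
        self, manifest: RequestManifest, sequence_no: int, due: datetime
    ) -> list[QueryInstance]:
        instances = []
        qid = make_query_id(manifest.request_id, sequence_no)
        for node_id in sorted(manifest.target_nodes):
            inst = QueryInstance(
                query_id=qid,
                request_id=manifest.request_id,
                sequence_no=sequence_no,
                due_time=due,
            )
            self._queues[node_id].append(inst)
            instances.append(inst)
        return instances

    def tick(
        self, now: Optional[datetime] = None, request_id: Optional[str] = None
    ) -> int:
        """Generate all series emissions due by ``now``; returns the count.

        ``request_id`` restricts the scan to one series (an optimization
        for callers that know which schedule advanced).
        """
        now = now if now is not None else self.clock.now()
        emitted = 0
        cursors = (
            list(self._next_emission.items())
            if request_id is None
            else [(request_id, self._next_emission[request_id])]
            if request_id in self._next_emission
            else []
        )
        for request_id, next_seq in cursors:
            manifest = self._manifests[request_id]
            assert manifest.series_interval is not None
            while True:
                if (
                    manifest.series_count is not None
                    and next_seq >= manifest.series_count
                ):
                    break
                due = manifest.execution_date + next_seq * manifest.series_interval
                if due > now:
                    break
                self._emit(manifest, sequence_no=next_seq, due=due)
                next_seq += 1
                emitted += 1
            self._next_emission[request_id] = next_seq
        return emitted

    def get_manifest(self, request_id: str) -> RequestManifest:
        try:
            return self._manifests[request_id]
        except KeyError:
            raise UnknownQuery(request_id) from None

    # -- node-facing operations -------------------------------------------

    def poll(
        self, node_id: str, api_key: str, now: Optional[datetime] = None
    ) -> list[QueryInstance]:
        """Deliver not-yet-delivered instances; idempotent on re-poll."""
        self._auth(node_id, api_key)
        now = now if now is not None else self.clock.now()
        delivered = []
        for inst in self._queues[node_id]:
            self._deliveries[(node_id, inst.query_id)] = _Delivery(
                node_id=node_id, query=inst, state=QueryState.RETRIEVED
            )
            self._append_event(
                ProvenanceEvent(
                    timestamp=now,
                    node_id=node_id,
                    query_id=inst.query_id,
                    from_state=None,
                    to_state=QueryState.RETRIEVED,
                    actor="system",
                )
            )
            delivered.append(inst)
        self._queues[node_id] = []
        return delivered

    def report_status(
        self,
        node_id: str,
        api_key: str,
        query_id: str,
        event: LifecycleEvent,
        timestamp: Optional[datetime] = None,
        *,
        review: bool = False,
        actor: str = "user",
    ) -> ProvenanceEvent:
        """Apply one lifecycle event to a delivered query and log it.

        ``review`` is only meaningful with ``APPROVE``: it stores the
        review-mode flag that later routes ``EXEC_OK`` to ``INTERACTION``.
        """
        self._auth(node_id, api_key)
        delivery = self._deliveries.get((node_id, query_id))
        if delivery is None:
            raise UnknownQuery(f"{query_id} not delivered to {node_id}")
        timestamp = timestamp if timestamp is not None else self.clock.now()
        new_state = next_state(delivery.state, event, review=delivery.review)
        ev = ProvenanceEvent(
            timestamp=timestamp,
            node_id=node_id,
            query_id=query_id,
            from_state=delivery.state,
            to_state=new_state,
            actor=actor,
        )
        self._append_event(ev)
        if event is LifecycleEvent.APPROVE:
            delivery.review = review
        delivery.state = new_state
        return ev

    def upload_result(
        self,
        node_id: str,
        api_key: str,
        query_id: str,
        payload: str,
        timestamp: Optional[datetime] = None,
        *,
        actor: str = "user",
    ) -> None:
        """Store a result payload verbatim and record the completion.

        Legal from ``PROCESSING`` (non-review path, completes via
        ``EXEC_OK``) or from ``INTERACTION`` (release path).
        """
        self._auth(node_id, api_key)
        delivery = self._deliveries.get((node_id, query_id))
        if delivery is None:
            raise UnknownQuery(f"{query_id} not delivered to {node_id}")
        _validate_csv_payload(payload)
        if delivery.state is QueryState.PROCESSING and not delivery.review:
            event = LifecycleEvent.EXEC_OK
        elif delivery.state is QueryState.INTERACTION:
            event = LifecycleEvent.RELEASE
        else:
            raise IllegalTransition(
                f"cannot upload result for {query_id} in state {delivery.state.value}"
            )
        self._payloads[(node_id, query_id)] = payload
        self.report_status(
            node_id, api_key, query_id, event, timestamp, actor=actor
        )

    # -- aggregation, status, export --------------------------------------

    def get_payload(self, node_id: str, query_id: str) -> str:
        try:
            return self._payloads[(node_id, query_id)]
        except KeyError:
            raise NoResults(f"{node_id}/{query_id}") from None

    def aggregate_results(self, request_id: str) -> pd.DataFrame:
        """Concatenate node payloads for a request, node_id column prepended.

        Column order is first-seen across lexicographically sorted nodes;
        cells for columns a node did not report are empty strings.
        """
        if request_id not in self._manifests:
            raise UnknownQuery(request_id)
        frames = []
        keys = sorted(
            k for k in self._payloads if k[1].rpartition("#")[0] == request_id
        )
        for node_id, query_id in keys:
            df = pd.read_csv(
                io.StringIO(self._payloads[(node_id, query_id)]),
                dtype=str,
                keep_default_na=False,
            )
            df.insert(0, "node_id", node_id)
            frames.append(df)
        if not frames:
            raise NoResults(request_id)
        out = pd.concat(frames, axis=0, ignore_index=True, sort=False)
        return out.fillna("")

    def status_board(self, request_id: str) -> RequestStatusBoard:
        manifest = self.get_manifest(request_id)
        board = RequestStatusBoard(request_id=request_id)
        for node_id in sorted(manifest.target_nodes):
            states = [
                d.state
                for (n, q), d in self._deliveries.items()
                if n == node_id and d.query.request_id == request_id
            ]
            if states:
                board.states[node_id] = states[-1]
            board.has_result[node_id] = any(
                n == node_id and q.rpartition("#")[0] == request_id
                for (n, q) in self._payloads
            )
        return board

    @property
    def events(self) -> tuple[ProvenanceEvent, ...]:
        return tuple(self._events)

    def _append_event(self, ev: ProvenanceEvent) -> None:
        self._events.append(ev)
        log.debug(
            "state_change ts=%s node=%s query=%s from=%s to=%s actor=%s",
            ev.timestamp.isoformat(),
            ev.node_id,
            ev.query_id,
            ev.from_token,
            ev.to_state.value,
            ev.actor,
        )

    def export_event_log(self, path: Union[str, Path], fmt: str = "csv") -> None:
        if fmt == "csv":
            eventlog.write_csv(self._events, path)
        elif fmt == "jsonl":
            eventlog.write_jsonl(self._events, path)
        else:
            raise ValueError(f"unknown log format {fmt!r}")
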