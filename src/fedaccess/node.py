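"""Node client: the per-department endpoint enforcing local authorization.

The client polls the broker for new queries, presents them for a manual
approve/reject decision, auto-authorizes later emissions of an approved
series with identical syntax, executes queries against its local toy
datastore at their due time, and uploads result CSVs.  Every state
change is reported to the broker, which is the system of record.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass
from datetime import datetime
from typing import Optional

from .broker import Broker
from .clock import SystemClock
from .datastore import LocalDatastore
from .miniquery import MiniQueryError, run_mini_query
from .model import NodeQueryRecord, QueryInstance, RequestManifest
from .states import IllegalTransition, LifecycleEvent, QueryState

__all__ = ["AuthorizationRule", "NodeClient", "syntax_fingerprint", "auto_authorize"]

log = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def syntax_fingerprint(syntax_language: str, syntax_body: str) -> str:
    """Hash identifying 'identical syntax' for auto-authorization.

    Whitespace runs are collapsed (layout changes do not force a fresh
    manual approval); any other character change, including case, yields
    a different fingerprint.
    """
    normalized = _WS.sub(" ", syntax_body).strip()
    digest = hashlib.sha256(
        f"{syntax_language}\x00{normalized}".encode("utf-8")
    ).hexdigest()
    return digest


@dataclass
class AuthorizationRule:
    """Standing per-request authorization created by the first approval.

    ``retroactive`` rules also cover emissions that fell due before the
    grant, which is how long-delayed completions (hundreds of days) arise
    for periodic queries.
    """

    request_id: str
    syntax_fingerprint: str
    granted: bool
    retroactive: bool
    granted_at: datetime


def auto_authorize(
    query: QueryInstance,
    manifest: RequestManifest,
    rules: dict[str, AuthorizationRule],
) -> bool:
    """True iff a granted rule covers this emission with identical syntax."""
    rule = rules.get(query.request_id)
    if rule is None or not rule.granted:
        return False
    if query.sequence_no < 1 and not rule.retroactive:
        return False
    return rule.syntax_fingerprint == syntax_fingerprint(
        manifest.syntax_language, manifest.syntax_body
    )


class NodeClient:
    def __init__(
        self,
        node_id: str,
        api_key: str,
        broker: Broker,
        datastore: Optional[LocalDatastore] = None,
        clock=None,
        review_default: bool = False,
    ):
        self.node_id = node_id
        self.api_key = api_key
        self.broker = broker
        self.datastore = datastore if datastore is not None else LocalDatastore()
        self.clock = clock if clock is not None else SystemClock()
        self.review_default = review_default
        self.records: dict[str, NodeQueryRecord] = {}
        self.rules: dict[str, AuthorizationRule] = {}
        self._pending_payload: dict[str, str] = {}

    # -- polling ------------------------------------------------------------

    def sync(self, now: Optional[datetime] = None) -> list[NodeQueryRecord]:
        """Poll for new queries; returns the newly retrieved records.

        New instances enter RETRIEVED; emissions covered by a standing
        authorization rule are immediately moved to ACCEPTED by the
        auto-rule actor (a system-actor view + approval, no user touch).
        """
        now = now if now is not None else self.clock.now()
        self.broker.tick(now)
        new_records = []
        for inst in self.broker.poll(self.node_id, self.api_key, now=now):
            record = NodeQueryRecord(
                node_id=self.node_id, query=inst, state=QueryState.RETRIEVED
            )
            # mirror of the broker's delivery event
            record.append(self._delivery_event(inst.query_id))
            self.records[inst.query_id] = record
            log.info(
                "notification node=%s query=%s (email stub)",
                self.node_id,
                inst.query_id,
            )
            manifest = self.broker.get_manifest(inst.request_id)
            if auto_authorize(inst, manifest, self.rules):
                self._report(inst.query_id, LifecycleEvent.VIEWED, now, "auto-rule")
                self._report(inst.query_id, LifecycleEvent.APPROVE, now, "auto-rule")
            new_records.append(record)
        return new_records

    def _delivery_event(self, query_id):
        for ev in reversed(self.broker.events):
            if ev.query_id == query_id and ev.node_id == self.node_id:
                return ev
        raise LookupError(query_id)

    def _report(
        self,
        query_id: str,
        event: LifecycleEvent,
        now: Optional[datetime],
        actor: str,
        review: bool = False,
    ):
        ts = now if now is not None else self.clock.now()
        ev = self.broker.report_status(
            self.node_id,
            self.api_key,
            query_id,
            event,
            timestamp=ts,
            review=review,
            actor=actor,
        )
        self.records[query_id].append(ev)
        return ev

    # -- manual decisions ----------------------------------------------------

    def view(self, query_id: str, now: Optional[datetime] = None,
             actor: str = "user") -> QueryState:
        self._report(query_id, LifecycleEvent.VIEWED, now, actor)
        return self.records[query_id].state

    def decide(
        self,
        query_id: str,
        decision: str,
        review: Optional[bool] = None,
        actor: str = "user",
        now: Optional[datetime] = None,
        retroactive: bool = True,
    ) -> QueryState:
        """Approve or reject a SEEN query.

        Approving a series creates a standing :class:`AuthorizationRule`
        (retroactive by default) so later emissions with identical syntax
        skip the manual step.
        """
        record = self.records.get(query_id)
        if record is None:
            raise KeyError(query_id)
        if record.state is not QueryState.SEEN:
            raise IllegalTransition(
                f"decision requires SEEN, query {query_id} is {record.state.value}"
            )
        review = self.review_default if review is None else review
        ts = now if now is not None else self.clock.now()
        if decision == "approve":
            self._report(query_id, LifecycleEvent.APPROVE, ts, actor, review=review)
            record.review = review
            manifest = self.broker.get_manifest(record.query.request_id)
            if manifest.query_type == "series":
                self.rules[manifest.request_id] = AuthorizationRule(
                    request_id=manifest.request_id,
                    syntax_fingerprint=syntax_fingerprint(
                        manifest.syntax_language, manifest.syntax_body
                    ),
                    granted=True,
                    retroactive=retroactive,
                    granted_at=ts,
                )
        elif decision == "reject":
            self._report(query_id, LifecycleEvent.REJECT, ts, actor)
        else:
            raise ValueError(f"unknown decision {decision!r}")
        return record.state

    def revoke_rule(self, request_id: str) -> None:
        self.rules.pop(request_id, None)

    # -- execution -----------------------------------------------------------

    def execute(self, query_id: str, now: Optional[datetime] = None) -> QueryState:
        """Run an ACCEPTED query whose due time has been reached.

        Execution errors are not raised: they end the query in FAILED
        with a logged reason.  With review mode on, a successful result
        is parked in INTERACTION until released.
        """
        record = self.records.get(query_id)
        if record is None:
            raise KeyError(query_id)
        now = now if now is not None else self.clock.now()
        if record.state is not QueryState.ACCEPTED:
            raise IllegalTransition(
                f"execute requires ACCEPTED, query {query_id} is {record.state.value}"
            )
        if now < record.query.due_time:
            raise IllegalTransition(
                f"query {query_id} not due until {record.query.due_time.isoformat()}"
            )
        manifest = self.broker.get_manifest(record.query.request_id)
        self._report(query_id, LifecycleEvent.EXECUTION_DUE, now, "system")
        try:
            result = run_mini_query(
                manifest.syntax_language, manifest.syntax_body, self.datastore
            )
        except MiniQueryError as exc:
            record.failure_reason = str(exc)
            log.warning("execution failed node=%s query=%s: %s",
                        self.node_id, query_id, exc)
            self._report(query_id, LifecycleEvent.EXEC_ERROR, now, "system")
            return record.state
        payload = result.to_csv(index=False)
        if record.review:
            self._pending_payload[query_id] = payload
            self._report(query_id, LifecycleEvent.EXEC_OK, now, "system")
            record.result_ref = f"local://{self.node_id}/{query_id}"
        else:
            self.broker.upload_result(
                self.node_id, self.api_key, query_id, payload,
                timestamp=now, actor="system",
            )
            record.append(self.broker.events[-1])
            record.result_ref = f"broker://{self.node_id}/{query_id}"
        return record.state

    def run_due(self, now: Optional[datetime] = None) -> list[str]:
        """Execute every accepted query whose due time has passed."""
        now = now if now is not None else self.clock.now()
        executed = []
        for query_id, record in list(self.records.items()):
            if record.state is QueryState.ACCEPTED and record.query.due_time <= now:
                self.execute(query_id, now=now)
                executed.append(query_id)
        return executed

    def review_and_release(
        self, query_id: str, decision: str, now: Optional[datetime] = None,
        actor: str = "user",
    ) -> QueryState:
        record = self.records.get(query_id)
        if record is None:
            raise KeyError(query_id)
        if record.state is not QueryState.INTERACTION:
            raise IllegalTransition(
                f"review requires INTERACTION, query {query_id} is "
                f"{record.state.value}"
            )
        now = now if now is not None else self.clock.now()
        if decision == "release":
            payload = self._pending_payload.pop(query_id)
            self.broker.upload_result(
                self.node_id, self.api_key, query_id, payload,
                timestamp=now, actor=actor,
            )
            record.append(self.broker.events[-1])
            record.result_ref = f"broker://{self.node_id}/{query_id}"
        elif decision == "withhold":
            self._pending_payload.pop(query_id, None)
            self._report(query_id, LifecycleEvent.WITHHOLD_REJECT, now, actor)
            record.result_ref = None
        else:
            raise ValueError(f"unknown decision {decision!r}")
        return record.state
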