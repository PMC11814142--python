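"""Discrete-event simulator of network traffic and node behavior.

Drives a real :class:`~fedaccess.broker.Broker` through a virtual clock:
requests are published over an observation window, nodes (joining over
the years) poll for them, and each delivered query follows a drawn
trajectory — ignored, rejected after some latency, or approved after
some latency and then executed with a small failure probability.  Series
requests are decided once per node; the standing authorization then
auto-executes subsequent emissions, retroactively covering emissions
that fell due while the decision was pending (which is how long-delayed
periodic completions arise).

Response latencies follow a two-component lognormal mixture: a fast
majority and a heavy slow tail, the shape needed to combine a median of
a few days with a mean an order of magnitude larger.

Everything is seeded: a fixed seed yields a byte-identical event log.
"""

from __future__ import annotations

import heapq
import itertools
import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Optional

import numpy as np

from .broker import Broker
from .clock import VirtualClock
from .model import (
    CoverLetter,
    KPICategory,
    ProvenanceEvent,
    RequestManifest,
    Requester,
)
from .states import LifecycleEvent, QueryState

__all__ = [
    "BehaviorProfile",
    "NodeBehavior",
    "NetworkConfig",
    "InvalidConfig",
    "InfeasibleRow",
    "sample_response",
    "simulate_network",
    "paper_like_config",
    "make_fixture_log",
]

DAY = timedelta(days=1)


class InvalidConfig(Exception):
    pass


class InfeasibleRow(Exception):
    pass


@dataclass(frozen=True)
class BehaviorProfile:
    """Stochastic behavior of one node for one query class.

    Latency of a manual response (days) is a mixture: with probability
    ``1 - p_tail`` a lognormal with median ``fast_median_days``, else a
    slower lognormal tail.  Rejections draw their own (slower) latency.
    ``p_ignore`` leaves the query unanswered forever.
    """

    p_reject: float
    p_ignore: float
    p_fail: float
    p_review: float
    fast_median_days: float = 4.0
    fast_sigma: float = 1.0
    p_tail: float = 0.15
    tail_median_days: float = 45.0
    tail_sigma: float = 1.2
    reject_median_days: float = 38.0
    reject_sigma: float = 1.0
    p_review_stall: float = 0.1
    proc_median_s: float = 21.0
    proc_sigma: float = 1.2

    def validate(self) -> None:
        probs = {
            "p_reject": self.p_reject,
            "p_ignore": self.p_ignore,
            "p_fail": self.p_fail,
            "p_review": self.p_review,
            "p_tail": self.p_tail,
            "p_review_stall": self.p_review_stall,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidConfig(f"{name}={p} outside [0, 1]")
        if self.p_reject + self.p_ignore > 1.0:
            raise InvalidConfig("p_reject + p_ignore exceeds 1")
        for name in ("fast_median_days", "tail_median_days", "reject_median_days",
                     "proc_median_s"):
            if getattr(self, name) <= 0:
                raise InvalidConfig(f"{name} must be positive")


@dataclass
class NodeBehavior:
    join_date: datetime
    individual: BehaviorProfile
    periodic: BehaviorProfile


@dataclass
class NetworkConfig:
    """Traffic shape and node behavior for one simulation run."""

    nodes: dict[str, NodeBehavior]
    window_start: datetime
    window_end: datetime
    n_single_requests: int = 1075
    single_targets: tuple[int, int] = (1, 4)
    n_series: int = 200
    series_interval: timedelta = timedelta(days=7)
    series_emissions: tuple[int, int] = (15, 45)
    series_target_fraction: float = 0.18
    poll_delay_max_s: int = 7200
    seed: int = 0

    def validate(self) -> None:
        if not self.nodes:
            raise InvalidConfig("no nodes configured")
        if self.window_end <= self.window_start:
            raise InvalidConfig("empty observation window")
        for node_id, nb in self.nodes.items():
            if nb.join_date < self.window_start or nb.join_date > self.window_end:
                raise InvalidConfig(
                    f"node {node_id} joins outside the observation window"
                )
            nb.individual.validate()
            nb.periodic.validate()
        if self.single_targets[0] < 1 or self.single_targets[0] > self.single_targets[1]:
            raise InvalidConfig("bad single_targets range")
        if self.series_emissions[0] < 1 or self.series_emissions[0] > self.series_emissions[1]:
            raise InvalidConfig("bad series_emissions range")
        if not 0 < self.series_target_fraction <= 1:
            raise InvalidConfig("series_target_fraction outside (0, 1]")


def _lognormal_days(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def sample_response(
    profile: BehaviorProfile, rng: np.random.Generator
) -> tuple[str, float]:
    """Draw one (action, latency_days) response.

    Action is multinomial over ignore/reject/approve; latency is drawn
    from the approval mixture (approve), the rejection lognormal
    (reject), or is ``inf`` (ignore).
    """
    u = rng.random()
    if u < profile.p_ignore:
        return "ignore", math.inf
    if u < profile.p_ignore + profile.p_reject:
        return "reject", _lognormal_days(
            rng, profile.reject_median_days, profile.reject_sigma
        )
    if rng.random() < profile.p_tail:
        latency = _lognormal_days(rng, profile.tail_median_days, profile.tail_sigma)
    else:
        latency = _lognormal_days(rng, profile.fast_median_days, profile.fast_sigma)
    return "approve", latency


# ---------------------------------------------------------------------------
# paper-like defaults

def paper_like_config(seed: int = 0, n_nodes: int = 58) -> NetworkConfig:
    """Default network emulating the operating conditions of a nationwide
    federated registry: 58 nodes joining 2017-2024 (12 in the first
    year), a 2017-11-11..2024-10-21 window, roughly 5% individual and
    95% periodic query instances (~50k in total), individual
    reject/ignore/fail probabilities 0.03/0.14/0.028 and periodic (per
    node-series decision) 0.01/0.11/0.01, and a fast-median-4-days
    latency mixture with a heavy tail.

    Node latency medians get mild multiplicative heterogeneity so
    per-node curves differ, as real nodes' do.
    """
    start = datetime(2017, 11, 11, tzinfo=timezone.utc)
    end = datetime(2024, 10, 21, tzinfo=timezone.utc)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xBEEF]))
    nodes: dict[str, NodeBehavior] = {}
    join_horizon = datetime(2024, 6, 1, tzinfo=timezone.utc)
    for i in range(n_nodes):
        if i < max(1, round(n_nodes * 12 / 58)):
            join = start + timedelta(days=float(rng.uniform(0, 45)))
        else:
            join = datetime(2018, 1, 1, tzinfo=timezone.utc) + timedelta(
                days=float(rng.uniform(0, (join_horizon - datetime(2018, 1, 1,
                    tzinfo=timezone.utc)).days))
            )
        speed = math.exp(0.25 * rng.standard_normal())  # node heterogeneity
        individual = BehaviorProfile(
            p_reject=0.03, p_ignore=0.14, p_fail=0.028, p_review=0.01,
            fast_median_days=4.0 * speed,
            proc_median_s=21.0, proc_sigma=1.2,
        )
        periodic = BehaviorProfile(
            p_reject=0.01, p_ignore=0.11, p_fail=0.01, p_review=0.0005,
            fast_median_days=4.0 * speed, p_review_stall=0.5,
            proc_median_s=12.0, proc_sigma=0.8,
        )
        nodes[f"ED-{i + 1:02d}"] = NodeBehavior(
            join_date=min(join, end), individual=individual, periodic=periodic
        )
    return NetworkConfig(
        nodes=nodes, window_start=start, window_end=end, seed=seed
    )


# ---------------------------------------------------------------------------
# the event loop

_LETTER = CoverLetter(
    rationale="Synthetic load generated for system evaluation.",
    research_questions_and_outcomes="Operational KPI measurement.",
    inclusion_criteria_and_variables="All synthetic encounters.",
    processors_and_purpose="Simulation harness; no real data processed.",
    ethics_and_privacy_commitments="No personal data involved.",
)


@dataclass
class _SeriesState:
    status: str = "pending"  # pending | approved | rejected | ignored
    pending: list[tuple[str, datetime]] = field(default_factory=list)
    decided: bool = False


class _Simulation:
    def __init__(self, config: NetworkConfig):
        config.validate()
        self.config = config
        self.clock = VirtualClock(config.window_start)
        self.broker = Broker(clock=self.clock)
        ss = np.random.SeedSequence(config.seed)
        children = ss.spawn(len(config.nodes) + 1)
        self.rng = np.random.default_rng(children[0])  # request planning
        self.node_rng = {
            node_id: np.random.default_rng(child)
            for node_id, child in zip(sorted(config.nodes), children[1:])
        }
        self.keys: dict[str, str] = {}
        self.heap: list = []
        self.counter = itertools.count()
        self.series_state: dict[tuple[str, str], _SeriesState] = {}
        self.manual_decisions = 0

    # scheduling helpers ----------------------------------------------------

    def push(self, ts: datetime, kind: str, *args) -> None:
        heapq.heappush(self.heap, (ts, next(self.counter), kind, args))

    def _active_nodes(self, ts: datetime) -> list[str]:
        return [
            n for n, nb in sorted(self.config.nodes.items()) if nb.join_date <= ts
        ]

    def _biased_time(self) -> datetime:
        # density increasing linearly over the window: traffic grows with
        # the network
        span = (self.config.window_end - self.config.window_start).total_seconds()
        u = self.rng.random()
        return self.config.window_start + timedelta(seconds=span * math.sqrt(u))

    def _poll_delay(self, node_id: str) -> timedelta:
        return timedelta(
            seconds=float(self.node_rng[node_id].uniform(
                60, self.config.poll_delay_max_s))
        )

    # request planning ------------------------------------------------------

    def plan_requests(self) -> None:
        cfg = self.config
        req_no = itertools.count(1)
        plans = []
        for _ in range(cfg.n_single_requests):
            plans.append(("single", self._biased_time()))
        for _ in range(cfg.n_series):
            plans.append(("series", self._biased_time()))
        plans.sort(key=lambda p: p[1])
        for kind, ts in plans:
            active = self._active_nodes(ts)
            if not active:
                continue
            request_id = f"R{next(req_no):05d}"
            if kind == "single":
                k = int(self.rng.integers(cfg.single_targets[0],
                                          cfg.single_targets[1] + 1))
                targets = self.rng.choice(active, size=min(k, len(active)),
                                          replace=False)
                manifest = RequestManifest(
                    request_id=request_id,
                    query_type="single",
                    syntax_language="sql",
                    syntax_body="SELECT triage_level, COUNT(*) FROM encounters "
                                "GROUP BY triage_level",
                    requester=Requester("Synthetic Requester", "Simulation", "sim@example.org"),
                    reference_date=ts,
                    execution_date=ts,
                    cover_letter=_LETTER,
                    target_nodes=frozenset(str(t) for t in targets),
                )
            else:
                n_emissions = int(self.rng.integers(cfg.series_emissions[0],
                                                    cfg.series_emissions[1] + 1))
                max_fit = int((cfg.window_end - ts) / cfg.series_interval) + 1
                n_emissions = max(1, min(n_emissions, max_fit))
                k = max(1, round(cfg.series_target_fraction * len(active)))
                targets = self.rng.choice(active, size=min(k, len(active)),
                                          replace=False)
                manifest = RequestManifest(
                    request_id=request_id,
                    query_type="series",
                    syntax_language="sql",
                    syntax_body="SELECT diagnosis_code, COUNT(*) FROM encounters "
                                "GROUP BY diagnosis_code",
                    requester=Requester("Synthetic Requester", "Simulation", "sim@example.org"),
                    reference_date=ts,
                    execution_date=ts,
                    cover_letter=_LETTER,
                    target_nodes=frozenset(str(t) for t in targets),
                    series_interval=cfg.series_interval,
                    series_count=n_emissions,
                )
            self.push(ts, "publish", manifest)

    # event handlers ---------------------------------------------------------

    def handle_publish(self, ts: datetime, manifest: RequestManifest) -> None:
        self.broker.publish_request(manifest, now=ts)
        n_emissions = manifest.series_count or 1
        for node_id in sorted(manifest.target_nodes):
            for k in range(n_emissions):
                due = manifest.execution_date + (
                    k * manifest.series_interval
                    if manifest.series_interval is not None
                    else timedelta(0)
                )
                self.push(max(ts, due) + self._poll_delay(node_id),
                          "poll", node_id, manifest.request_id)

    def handle_poll(self, ts: datetime, node_id: str, request_id: str) -> None:
        self.broker.tick(ts, request_id=request_id)
        for inst in self.broker.poll(node_id, self.keys[node_id], now=ts):
            manifest = self.broker.get_manifest(inst.request_id)
            if manifest.query_type == "single":
                self._plan_single(ts, node_id, inst.query_id)
            else:
                self._plan_series_emission(ts, node_id, inst)

    def _report(self, ts, node_id, query_id, event, actor, review=False):
        self.broker.report_status(
            node_id, self.keys[node_id], query_id, event,
            timestamp=ts, review=review, actor=actor,
        )

    def _plan_single(self, ts: datetime, node_id: str, query_id: str) -> None:
        profile = self.config.nodes[node_id].individual
        rng = self.node_rng[node_id]
        action, latency = sample_response(profile, rng)
        self.manual_decisions += 1
        if action == "ignore":
            if rng.random() < 0.5:  # opened but never decided
                self.push(ts + timedelta(days=float(rng.uniform(1, 20))),
                          "report", node_id, query_id, LifecycleEvent.VIEWED, "user")
            return
        t1 = ts + timedelta(days=latency)
        if action == "reject":
            self.push(t1, "reject", node_id, query_id, "user")
        else:
            review = bool(rng.random() < profile.p_review)
            self.push(t1, "approve_execute", node_id, query_id, "user", review,
                      "individual")

    def _plan_series_emission(self, ts, node_id, inst) -> None:
        key = (node_id, inst.request_id)
        state = self.series_state.get(key)
        if state is None:
            state = _SeriesState()
            self.series_state[key] = state
            profile = self.config.nodes[node_id].periodic
            action, latency = sample_response(profile, self.node_rng[node_id])
            self.manual_decisions += 1
            state.pending.append((inst.query_id, ts))
            if action != "ignore":
                self.push(ts + timedelta(days=latency),
                          "series_decide", node_id, inst.request_id, action)
            else:
                state.status = "ignored"
            return
        if state.status in ("pending", "ignored"):
            if state.status == "pending":
                state.pending.append((inst.query_id, ts))
            return
        actor = "auto-rule"
        if state.status == "approved":
            self.push(ts, "approve_execute", node_id, inst.query_id, actor,
                      False, "periodic")
        else:  # rejected series: future emissions auto-rejected
            self.push(ts, "reject", node_id, inst.query_id, actor)

    def handle_series_decide(self, ts, node_id, request_id, action) -> None:
        state = self.series_state[(node_id, request_id)]
        state.status = "approved" if action == "approve" else "rejected"
        first = True
        for query_id, _retrieved in state.pending:
            actor = "user" if first else "auto-rule"
            if action == "approve":
                profile = self.config.nodes[node_id].periodic
                review = bool(self.node_rng[node_id].random() < profile.p_review)
                self.push(ts, "approve_execute", node_id, query_id, actor,
                          review, "periodic")
            else:
                self.push(ts, "reject", node_id, query_id, actor)
            first = False
        state.pending.clear()

    def handle_reject(self, ts, node_id, query_id, actor) -> None:
        self._report(ts, node_id, query_id, LifecycleEvent.VIEWED, actor)
        self._report(ts, node_id, query_id, LifecycleEvent.REJECT, actor)

    def handle_approve_execute(self, ts, node_id, query_id, actor, review,
                               cls) -> None:
        profile = getattr(self.config.nodes[node_id], cls)
        rng = self.node_rng[node_id]
        self._report(ts, node_id, query_id, LifecycleEvent.VIEWED, actor)
        self._report(ts, node_id, query_id, LifecycleEvent.APPROVE, actor,
                     review=review)
        self._report(ts, node_id, query_id, LifecycleEvent.EXECUTION_DUE, "system")
        proc = timedelta(seconds=_lognormal_days(rng, profile.proc_median_s,
                                                 profile.proc_sigma))
        t2 = ts + proc
        if rng.random() < profile.p_fail:
            self.push(t2, "report", node_id, query_id, LifecycleEvent.EXEC_ERROR,
                      "system")
            return
        self.push(t2, "report", node_id, query_id, LifecycleEvent.EXEC_OK, "system")
        if review:
            if rng.random() >= profile.p_review_stall:
                t3 = t2 + timedelta(days=float(rng.uniform(0.5, 5)))
                self.push(t3, "report", node_id, query_id, LifecycleEvent.RELEASE,
                          "user")

    def handle_report(self, ts, node_id, query_id, event, actor) -> None:
        self._report(ts, node_id, query_id, event, actor)

    # main loop ---------------------------------------------------------------

    def run(self) -> list[ProvenanceEvent]:
        for node_id, nb in sorted(self.config.nodes.items()):
            reg = self.broker.register_node(node_id, joined=nb.join_date)
            self.keys[node_id] = reg.api_key
        self.plan_requests()
        handlers = {
            "publish": self.handle_publish,
            "poll": self.handle_poll,
            "series_decide": self.handle_series_decide,
            "reject": self.handle_reject,
            "approve_execute": self.handle_approve_execute,
            "report": self.handle_report,
        }
        while self.heap:
            ts, _count, kind, args = heapq.heappop(self.heap)
            self.clock.set(ts)
            handlers[kind](ts, *args)
        # The log is "extracted" at window_end: later events do not exist,
        # leaving their queries censored mid-workflow, exactly as a real
        # retrospective log extraction would.
        return [
            ev for ev in self.broker.events
            if ev.timestamp <= self.config.window_end
        ]


def simulate_network(config: NetworkConfig) -> list[ProvenanceEvent]:
    """Run the network simulation; returns the provenance event log."""
    return _Simulation(config).run()


# ---------------------------------------------------------------------------
# deterministic fixture builder

_FIXTURE_BASE = datetime(2020, 1, 1, 8, 0, 0, tzinfo=timezone.utc)

_NEEDS_DAYS = {
    KPICategory.COMPLETED,
    KPICategory.FAILED,
    KPICategory.REJECTED,
    KPICategory.REVIEW_UNANSWERED,
    KPICategory.PENDING_OTHER,
}


def make_fixture_log(
    rows: list[tuple[str, str, KPICategory, Optional[int]]],
    base: datetime = _FIXTURE_BASE,
) -> list[ProvenanceEvent]:
    """Emit a minimal legal event sequence realizing each row exactly.

    Each row is ``(node_id, query_id, terminal_category, days)`` where
    ``days`` is the whole-day offset of the category-defining event from
    retrieval (ignored for UNANSWERED).  Deterministic: row *i* is
    retrieved at ``base + i`` seconds.
    """
    events: list[ProvenanceEvent] = []

    def emit(ts, node, query, from_state, to_state):
        events.append(
            ProvenanceEvent(
                timestamp=ts, node_id=node, query_id=query,
                from_state=from_state, to_state=to_state, actor="system",
            )
        )

    for i, (node_id, query_id, category, days) in enumerate(rows):
        category = KPICategory(category)
        if category in _NEEDS_DAYS:
            if days is None or days < 0:
                raise InfeasibleRow(
                    f"row {i}: category {category.value} needs days >= 0"
                )
        t0 = base + timedelta(seconds=i)
        t1 = t0 + timedelta(days=days or 0)
        emit(t0, node_id, query_id, None, QueryState.RETRIEVED)
        if category is KPICategory.UNANSWERED:
            continue
        emit(t0, node_id, query_id, QueryState.RETRIEVED, QueryState.SEEN)
        if category is KPICategory.REJECTED:
            emit(t1, node_id, query_id, QueryState.SEEN, QueryState.REJECTED)
            continue
        if category is KPICategory.PENDING_OTHER:
            emit(t1, node_id, query_id, QueryState.SEEN, QueryState.ACCEPTED)
            continue
        emit(t0, node_id, query_id, QueryState.SEEN, QueryState.ACCEPTED)
        emit(t1, node_id, query_id, QueryState.ACCEPTED, QueryState.PROCESSING)
        if category is KPICategory.COMPLETED:
            emit(t1, node_id, query_id, QueryState.PROCESSING, QueryState.COMPLETED)
        elif category is KPICategory.FAILED:
            emit(t1, node_id, query_id, QueryState.PROCESSING, QueryState.FAILED)
        else:  # REVIEW_UNANSWERED
            emit(t1, node_id, query_id, QueryState.PROCESSING,
                 QueryState.INTERACTION)
    return events
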