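"""KPI analytics over provenance event logs.

Reconstructs per-query histories from a log, classifies each query at a
cutoff into six mutually exclusive categories (completed, failed,
rejected, unanswered, opened-for-review-but-unanswered, pending-other),
and computes the operational statistics used to evaluate a federated
authorization network: per-class rates, completion/rejection timing,
processing durations, yearly volumes and active-node counts, Kaplan–
Meier curves of the proportion of still-uncompleted queries over days
since retrieval, and a paired per-node comparison of individual versus
periodic completion times.

Conventions: elapsed days are ``floor((t1 - t0) / 1 day)`` so immediate
auto-executed completions are day 0; percentages are rounded half-up to
one decimal; SDs use the n-1 denominator; percentiles use linear
interpolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from decimal import Decimal, ROUND_HALF_UP

from . import eventlog
from .model import KPICategory, NodeQueryRecord, categorize
from .states import QueryState

__all__ = [
    "EmptyInput",
    "NoCompletions",
    "NoResponses",
    "InsufficientPairs",
    "UnknownDialect",
    "LoadResult",
    "KMCurve",
    "TimingStats",
    "KPIReport",
    "load_event_log",
    "records_from_events",
    "exclude_nodes",
    "split_classes",
    "rate_percent",
    "compute_rates",
    "completion_time_stats",
    "km_uncompleted",
    "per_node_curves",
    "yearly_summary",
    "percentile_time",
    "paired_class_comparison",
    "build_report",
]

SECONDS_PER_DAY = 86400.0

CLASSES = ("individual", "periodic", "all")

CATEGORY_ORDER = (
    KPICategory.COMPLETED,
    KPICategory.FAILED,
    KPICategory.REVIEW_UNANSWERED,
    KPICategory.UNANSWERED,
    KPICategory.REJECTED,
    KPICategory.PENDING_OTHER,
)


class EmptyInput(Exception):
    pass


class NoCompletions(Exception):
    pass


class NoResponses(Exception):
    pass


class InsufficientPairs(Exception):
    pass


class UnknownDialect(Exception):
    pass


# ---------------------------------------------------------------------------
# loading

records_from_events = eventlog.records_from_events  # re-export at analysis surface


@dataclass
class LoadResult:
    records: list[NodeQueryRecord]
    quarantined: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def load_event_log(
    path: Union[str, Path],
    dialect: str = "native",
    strict: bool = True,
    **dialect_options,
) -> LoadResult:
    """Read an event log and reconstruct per-query records.

    ``dialect="native"`` reads the package's own CSV/JSONL formats;
    ``dialect="zenodo"`` goes through the deposit adapter (see
    :mod:`fedaccess.zenodo`).  Strict mode raises
    :class:`fedaccess.eventlog.ParseError` naming the first query whose
    history violates the transition graph; lenient mode quarantines such
    queries and counts them.
    """
    path = Path(path)
    if dialect == "native":
        if path.suffix == ".jsonl":
            events = eventlog.read_jsonl(path)
        else:
            events = eventlog.read_csv(path)
    elif dialect == "zenodo":
        from .zenodo import read_deposit_events

        events = read_deposit_events(path, **dialect_options)
    else:
        raise UnknownDialect(dialect)
    records, quarantined = eventlog.records_from_events(events, strict=strict)
    return LoadResult(records=records, quarantined=quarantined)


def exclude_nodes(
    records: Sequence[NodeQueryRecord], inactive: Iterable[str]
) -> tuple[list[NodeQueryRecord], int]:
    """Drop all records of the listed nodes; returns (kept, n_dropped)."""
    inactive = set(inactive)
    kept = [r for r in records if r.node_id not in inactive]
    return kept, len(records) - len(kept)


def periodic_request_ids(records: Sequence[NodeQueryRecord]) -> set[str]:
    """Requests observed with an emission beyond the first are periodic."""
    return {r.query.request_id for r in records if r.query.sequence_no >= 1}


def split_classes(
    records: Sequence[NodeQueryRecord],
    periodic_requests: Optional[set[str]] = None,
) -> dict[str, list[NodeQueryRecord]]:
    """Partition records into individual / periodic / all."""
    if periodic_requests is None:
        periodic_requests = periodic_request_ids(records)
    individual = [r for r in records if r.query.request_id not in periodic_requests]
    periodic = [r for r in records if r.query.request_id in periodic_requests]
    return {"individual": individual, "periodic": periodic, "all": list(records)}


# ---------------------------------------------------------------------------
# rates

def rate_percent(count: int, total: int) -> float:
    """Percentage at one decimal, rounded half-up on the exact rational."""
    if total <= 0:
        raise EmptyInput("rate over an empty total")
    exact = Decimal(100) * Decimal(count) / Decimal(total)
    return float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def category_counts(
    records: Sequence[NodeQueryRecord], cutoff: datetime
) -> dict[KPICategory, int]:
    counts = {cat: 0 for cat in CATEGORY_ORDER}
    for record in records:
        counts[categorize(record, cutoff)] += 1
    return counts


def compute_rates(
    records: Sequence[NodeQueryRecord],
    cutoff: datetime,
    periodic_requests: Optional[set[str]] = None,
) -> dict[str, dict[str, dict[str, float | int]]]:
    """Per-class category counts and one-decimal percentage rates.

    Returns ``{class: {"total": n, "counts": {...}, "rates": {...}}}``
    for the classes individual, periodic and all.  Rates within a class
    are percentages of that class's total.
    """
    if not records:
        raise EmptyInput("no records")
    out: dict[str, dict] = {}
    for cls, recs in split_classes(records, periodic_requests).items():
        counts = category_counts(recs, cutoff) if recs else {
            cat: 0 for cat in CATEGORY_ORDER
        }
        total = len(recs)
        out[cls] = {
            "total": total,
            "counts": {cat.value: n for cat, n in counts.items()},
            "rates": {
                cat.value: (rate_percent(n, total) if total else math.nan)
                for cat, n in counts.items()
            },
        }
    return out


# ---------------------------------------------------------------------------
# timing

def days_between(t0: datetime, t1: datetime) -> int:
    """Elapsed whole days (floor convention)."""
    return int(math.floor((t1 - t0).total_seconds() / SECONDS_PER_DAY))


def _first_time_in(record: NodeQueryRecord, states: frozenset | set) -> Optional[datetime]:
    for ev in record.history:
        if ev.to_state in states:
            return ev.timestamp
    return None


def completion_days(record: NodeQueryRecord) -> Optional[int]:
    t = _first_time_in(record, {QueryState.COMPLETED})
    return None if t is None else days_between(record.retrieved_at, t)


def rejection_days(record: NodeQueryRecord) -> Optional[int]:
    t = _first_time_in(record, {QueryState.REJECTED})
    return None if t is None else days_between(record.retrieved_at, t)


def processing_seconds(record: NodeQueryRecord) -> Optional[float]:
    """Seconds from entering PROCESSING to leaving it."""
    start = None
    for ev in record.history:
        if ev.to_state is QueryState.PROCESSING:
            start = ev.timestamp
        elif start is not None:
            return (ev.timestamp - start).total_seconds()
    return None


@dataclass
class TimingStats:
    n_completed: int
    mean_days: float
    sd_days: float
    median_days: float
    min_days: int
    max_days: int
    n_rejected: int
    rejection_median_days: Optional[float]
    rejection_sd_days: Optional[float]
    n_processed: int
    processing_median_s: Optional[float]
    processing_iqr_s: Optional[tuple[float, float]]


def completion_time_stats(records: Sequence[NodeQueryRecord]) -> TimingStats:
    """Timing statistics for one class of records.

    Days to completion/rejection use the floor convention; SD is the
    sample SD (n-1); quartiles use linear interpolation.
    """
    comp = np.array(
        [d for d in (completion_days(r) for r in records) if d is not None],
        dtype=float,
    )
    if comp.size == 0:
        raise NoCompletions("no completed records")
    rej = np.array(
        [d for d in (rejection_days(r) for r in records) if d is not None],
        dtype=float,
    )
    proc = np.array(
        [s for s in (processing_seconds(r) for r in records) if s is not None],
        dtype=float,
    )
    return TimingStats(
        n_completed=int(comp.size),
        mean_days=float(comp.mean()),
        sd_days=float(comp.std(ddof=1)) if comp.size > 1 else 0.0,
        median_days=float(np.median(comp)),
        min_days=int(comp.min()),
        max_days=int(comp.max()),
        n_rejected=int(rej.size),
        rejection_median_days=float(np.median(rej)) if rej.size else None,
        rejection_sd_days=(
            float(rej.std(ddof=1)) if rej.size > 1 else (0.0 if rej.size else None)
        ),
        n_processed=int(proc.size),
        processing_median_s=float(np.median(proc)) if proc.size else None,
        processing_iqr_s=(
            (float(np.percentile(proc, 25)), float(np.percentile(proc, 75)))
            if proc.size
            else None
        ),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass
class KMCurve:
    """Kaplan-Meier estimate of the proportion of uncompleted queries.

    ``times`` are whole days since retrieval at which anything was
    observed; ``at_risk``/``events``/``censored`` are the n/d/c counts
    and ``survival`` the product-limit S(t).  Censoring at a time is
    conventionally processed after events at that time (censored items
    are still at risk for same-day events).
    """

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    survival: np.ndarray

    @classmethod
    def from_durations(
        cls, event_days: Sequence[int], censored_days: Sequence[int]
    ) -> "KMCurve":
        event_days = np.asarray(sorted(event_days), dtype=int)
        censored_days = np.asarray(sorted(censored_days), dtype=int)
        n = event_days.size + censored_days.size
        if n == 0:
            raise EmptyInput("no observations")
        times = np.unique(np.concatenate([event_days, censored_days]))
        at_risk = np.empty(times.size, dtype=int)
        d = np.empty(times.size, dtype=int)
        c = np.empty(times.size, dtype=int)
        surv = np.empty(times.size, dtype=float)
        s = 1.0
        remaining = n
        for i, t in enumerate(times):
            at_risk[i] = remaining
            d[i] = int((event_days == t).sum())
            c[i] = int((censored_days == t).sum())
            if d[i]:
                s *= 1.0 - d[i] / remaining
            surv[i] = s
            remaining -= d[i] + c[i]
        return cls(times=times, at_risk=at_risk, events=d, censored=c, survival=surv)

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_rows(self) -> list[dict[str, float | int]]:
        return [
            {
                "t": int(t),
                "n": int(n),
                "d": int(d),
                "c": int(c),
                "S": float(s),
            }
            for t, n, d, c, s in zip(
                self.times, self.at_risk, self.events, self.censored, self.survival
            )
        ]


def km_uncompleted(
    records: Sequence[NodeQueryRecord], cutoff: datetime
) -> KMCurve:
    """KM curve of completion, censoring everything else.

    The event is completion; rejection, failure, or still being open at
    the cutoff censor the query at min(terminal time, cutoff) days after
    retrieval.  Records retrieved after the cutoff are excluded.
    """
    events: list[int] = []
    censored: list[int] = []
    for record in records:
        t0 = record.retrieved_at
        if t0 > cutoff:
            continue
        terminal = record.terminal_time()
        if (
            record.state is QueryState.COMPLETED
            and terminal is not None
            and terminal <= cutoff
        ):
            events.append(days_between(t0, terminal))
        else:
            end = terminal if (terminal is not None and terminal <= cutoff) else cutoff
            censored.append(days_between(t0, end))
    if not events and not censored:
        raise EmptyInput("no records retrieved before cutoff")
    return KMCurve.from_durations(events, censored)


def per_node_curves(
    records: Sequence[NodeQueryRecord], cutoff: datetime
) -> dict[str, KMCurve]:
    """KM curve per node; nodes without usable records are omitted."""
    by_node: dict[str, list[NodeQueryRecord]] = {}
    for record in records:
        by_node.setdefault(record.node_id, []).append(record)
    curves = {}
    for node_id, recs in sorted(by_node.items()):
        try:
            curves[node_id] = km_uncompleted(recs, cutoff)
        except EmptyInput:
            continue
    return curves


# ---------------------------------------------------------------------------
# volumes, percentiles, paired comparison

def yearly_summary(
    records: Sequence[NodeQueryRecord],
) -> dict[int, dict[str, int]]:
    """Per calendar year (UTC): query volume and active node count.

    A query belongs to the year of its retrieval; a node is active in a
    year if it has at least one provenance event that year.
    """
    volumes: dict[int, int] = {}
    active: dict[int, set[str]] = {}
    for record in records:
        volumes[record.retrieved_at.year] = volumes.get(record.retrieved_at.year, 0) + 1
        for ev in record.history:
            active.setdefault(ev.timestamp.year, set()).add(ev.node_id)
    years = sorted(set(volumes) | set(active))
    return {
        y: {"queries": volumes.get(y, 0), "active_nodes": len(active.get(y, set()))}
        for y in years
    }


def percentile_time(records: Sequence[NodeQueryRecord], q: float) -> float:
    """q-th percentile of days from retrieval to any terminal response.

    'Response' pools completions, rejections and failures; linear
    interpolation between order statistics.
    """
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    days = [
        days_between(r.retrieved_at, t)
        for r in records
        for t in [r.terminal_time()]
        if t is not None
    ]
    if not days:
        raise NoResponses("no terminal records")
    return float(np.percentile(np.asarray(days, dtype=float), q))


def paired_class_comparison(
    records: Sequence[NodeQueryRecord],
    periodic_requests: Optional[set[str]] = None,
) -> dict[str, float]:
    """Paired t-test of per-node mean completion days, individual vs periodic.

    Pairs are nodes with at least one completed query in both classes.
    Returns ``{"t": ..., "p": ..., "n_pairs": ...}``; the degenerate
    constant-shift case reports t of ±inf with p = 0.
    """
    classes = split_classes(records, periodic_requests)
    means: dict[str, dict[str, float]] = {"individual": {}, "periodic": {}}
    for cls in ("individual", "periodic"):
        by_node: dict[str, list[int]] = {}
        for record in classes[cls]:
            d = completion_days(record)
            if d is not None:
                by_node.setdefault(record.node_id, []).append(d)
        means[cls] = {n: float(np.mean(v)) for n, v in by_node.items()}
    nodes = sorted(set(means["individual"]) & set(means["periodic"]))
    if len(nodes) < 2:
        raise InsufficientPairs(f"{len(nodes)} node(s) with completions in both classes")
    diffs = np.array(
        [means["individual"][n] - means["periodic"][n] for n in nodes], dtype=float
    )
    sd = diffs.std(ddof=1)
    n = diffs.size
    if sd == 0.0:
        if diffs.mean() == 0.0:
            return {"t": 0.0, "p": 1.0, "n_pairs": n}
        return {"t": math.copysign(math.inf, diffs.mean()), "p": 0.0, "n_pairs": n}
    from scipy import stats

    t = diffs.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return {"t": float(t), "p": float(p), "n_pairs": int(n)}


# ---------------------------------------------------------------------------
# report assembly

@dataclass
class KPIReport:
    cutoff: datetime
    rates: dict
    timing: dict[str, Optional[TimingStats]]
    yearly: dict[int, dict[str, int]]
    response_p75_days: Optional[float]
    paired: Optional[dict[str, float]]
    n_quarantined: int = 0

    def to_dict(self) -> dict:
        def timing_dict(ts: Optional[TimingStats]):
            if ts is None:
                return None
            d = ts.__dict__.copy()
            if d["processing_iqr_s"] is not None:
                d["processing_iqr_s"] = list(d["processing_iqr_s"])
            return d

        return {
            "cutoff": self.cutoff.isoformat(),
            "rates": self.rates,
            "timing": {cls: timing_dict(ts) for cls, ts in self.timing.items()},
            "yearly": {str(y): v for y, v in self.yearly.items()},
            "response_p75_days": self.response_p75_days,
            "paired_individual_vs_periodic": self.paired,
            "n_quarantined": self.n_quarantined,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_text(self) -> str:
        lines = [f"KPI report (cutoff {self.cutoff.isoformat()})", ""]
        header = f"{'category':<20}" + "".join(f"{cls:>14}" for cls in CLASSES)
        lines.append(header)
        for cat in CATEGORY_ORDER:
            row = f"{cat.value:<20}"
            for cls in CLASSES:
                n = self.rates[cls]["counts"][cat.value]
                pct = self.rates[cls]["rates"][cat.value]
                row += f"{pct:>7.1f}% {n:>5}" if not math.isnan(pct) else " " * 14
            lines.append(row)
        lines.append(
            f"{'total':<20}"
            + "".join(f"{self.rates[cls]['total']:>14}" for cls in CLASSES)
        )
        lines.append("")
        for cls in CLASSES:
            ts = self.timing.get(cls)
            if ts is None:
                continue
            lines.append(
                f"{cls}: completion days mean {ts.mean_days:.1f} "
                f"(SD {ts.sd_days:.1f}), median {ts.median_days:.0f}, "
                f"range {ts.min_days}-{ts.max_days} (n={ts.n_completed})"
            )
            if ts.processing_median_s is not None:
                q1, q3 = ts.processing_iqr_s
                lines.append(
                    f"{cls}: processing median {ts.processing_median_s:.0f} s "
                    f"(IQR {q1:.0f}-{q3:.0f})"
                )
        if self.response_p75_days is not None:
            lines.append(f"75th percentile of response time: "
                         f"{self.response_p75_days:.1f} days")
        if self.paired is not None:
            lines.append(
                f"paired t-test (per-node mean completion days, individual vs "
                f"periodic): t={self.paired['t']:.3f}, p={self.paired['p']:.3g}, "
                f"n={self.paired['n_pairs']}"
            )
        lines.append("")
        lines.append(f"{'year':<8}{'queries':>10}{'active nodes':>14}")
        for y, v in self.yearly.items():
            lines.append(f"{y:<8}{v['queries']:>10}{v['active_nodes']:>14}")
        return "\n".join(lines)


def build_report(
    records: Sequence[NodeQueryRecord],
    cutoff: datetime,
    periodic_requests: Optional[set[str]] = None,
    n_quarantined: int = 0,
) -> KPIReport:
    """Assemble the full KPI report for a record set at a cutoff."""
    if not records:
        raise EmptyInput("no records")
    if periodic_requests is None:
        periodic_requests = periodic_request_ids(records)
    rates = compute_rates(records, cutoff, periodic_requests)
    classes = split_classes(records, periodic_requests)
    timing: dict[str, Optional[TimingStats]] = {}
    for cls in CLASSES:
        try:
            timing[cls] = completion_time_stats(classes[cls])
        except NoCompletions:
            timing[cls] = None
    try:
        p75 = percentile_time(records, 75)
    except NoResponses:
        p75 = None
    try:
        paired = paired_class_comparison(records, periodic_requests)
    except InsufficientPairs:
        paired = None
    return KPIReport(
        cutoff=cutoff,
        rates=rates,
        timing=timing,
        yearly=yearly_summary(records),
        response_p75_days=p75,
        paired=paired,
        n_quarantined=n_quarantined,
    )
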