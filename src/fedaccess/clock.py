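"""Injectable clocks so broker/node scheduling is reproducible in tests."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

__all__ = ["SystemClock", "VirtualClock"]


class SystemClock:
    """Wall clock, UTC, second resolution."""

    def now(self) -> datetime:
        return datetime.now(timezone.utc).replace(microsecond=0)


class VirtualClock:
    """Manually advanced clock used by the simulator and the test suite."""

    def __init__(self, start: datetime):
        if start.tzinfo is None:
            start = start.replace(tzinfo=timezone.utc)
        self._now = start.astimezone(timezone.utc).replace(microsecond=0)

    def now(self) -> datetime:
        return self._now

    def advance(self, delta: timedelta) -> datetime:
        if delta < timedelta(0):
            raise ValueError("clock cannot move backwards")
        self._now += delta
        return self._now

    def set(self, ts: datetime) -> datetime:
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=timezone.utc)
        ts = ts.astimezone(timezone.utc).replace(microsecond=0)
        if ts < self._now:
            raise ValueError("clock cannot move backwards")
        self._now = ts
        return self._now
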