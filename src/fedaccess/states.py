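"""Authorization workflow state machine.

Every query delivered to a node walks a fixed transition graph: it is
*retrieved* by polling, *seen* when a user opens it, approved into an
*accepted* queue, *processed* at execution time, and ends *completed*,
*failed* or *rejected*.  An optional review mode inserts an *interaction*
state between successful execution and release of the result.
"""

from __future__ import annotations

import enum

__all__ = [
    "QueryState",
    "LifecycleEvent",
    "TERMINAL_STATES",
    "LEGAL_EDGES",
    "SENTINEL_NEW",
    "IllegalTransition",
    "UnknownEvent",
    "next_state",
]


class QueryState(str, enum.Enum):
    """States a query instance can be in at a node."""

    RETRIEVED = "RETRIEVED"
    SEEN = "SEEN"
    REJECTED = "REJECTED"
    ACCEPTED = "ACCEPTED"
    PROCESSING = "PROCESSING"
    FAILED = "FAILED"
    COMPLETED = "COMPLETED"
    INTERACTION = "INTERACTION"

    def __str__(self) -> str:  # stable serialization token
        return self.value


class LifecycleEvent(str, enum.Enum):
    """Events that drive transitions between :class:`QueryState` values."""

    POLLED = "POLLED"
    VIEWED = "VIEWED"
    APPROVE = "APPROVE"
    REJECT = "REJECT"
    EXECUTION_DUE = "EXECUTION_DUE"
    EXEC_OK = "EXEC_OK"
    EXEC_ERROR = "EXEC_ERROR"
    RELEASE = "RELEASE"
    WITHHOLD_REJECT = "WITHHOLD_REJECT"

    def __str__(self) -> str:
        return self.value


#: Terminal states: no outgoing transitions.
TERMINAL_STATES = frozenset(
    {QueryState.REJECTED, QueryState.FAILED, QueryState.COMPLETED}
)

#: Token used in provenance records for the pre-retrieval pseudo-state.
SENTINEL_NEW = "NEW"


class IllegalTransition(Exception):
    """Raised when an event is not legal from the current state."""


class UnknownEvent(Exception):
    """Raised when the event is not a :class:`LifecycleEvent`."""


# (state, event, review-branch) -> successor.  EXEC_OK is the only event
# whose successor depends on the review flag chosen at approval time.
_TRANSITIONS: dict[tuple[QueryState, LifecycleEvent, bool], QueryState] = {
    (QueryState.RETRIEVED, LifecycleEvent.VIEWED, False): QueryState.SEEN,
    (QueryState.SEEN, LifecycleEvent.REJECT, False): QueryState.REJECTED,
    (QueryState.SEEN, LifecycleEvent.APPROVE, False): QueryState.ACCEPTED,
    (QueryState.ACCEPTED, LifecycleEvent.EXECUTION_DUE, False): QueryState.PROCESSING,
    (QueryState.PROCESSING, LifecycleEvent.EXEC_ERROR, False): QueryState.FAILED,
    (QueryState.PROCESSING, LifecycleEvent.EXEC_OK, False): QueryState.COMPLETED,
    (QueryState.PROCESSING, LifecycleEvent.EXEC_OK, True): QueryState.INTERACTION,
    (QueryState.INTERACTION, LifecycleEvent.RELEASE, False): QueryState.COMPLETED,
    (QueryState.INTERACTION, LifecycleEvent.WITHHOLD_REJECT, False): QueryState.REJECTED,
}

#: The legal (from_state, to_state) edges of the workflow graph.
LEGAL_EDGES = frozenset((s, t) for (s, _e, _r), t in _TRANSITIONS.items())


def next_state(
    current: QueryState, event: LifecycleEvent, *, review: bool = False
) -> QueryState:
    """Return the successor state for ``event`` fired in ``current``.

    Pure function: illegal pairs raise :class:`IllegalTransition` without
    side effects.  ``review`` selects the branch of a successful execution:
    with review mode on, ``EXEC_OK`` parks the result in ``INTERACTION``
    for manual release instead of completing immediately.

    Raises
    ------
    UnknownEvent
        If ``event`` is not a :class:`LifecycleEvent`.
    IllegalTransition
        If the graph has no such edge (including any event fired in a
        terminal state).
    """
    if not isinstance(event, LifecycleEvent):
        raise UnknownEvent(f"not a lifecycle event: {event!r}")
    if not isinstance(current, QueryState):
        raise IllegalTransition(f"not a query state: {current!r}")
    key = (current, event, review if event is LifecycleEvent.EXEC_OK else False)
    try:
        return _TRANSITIONS[key]
    except KeyError:
        raise IllegalTransition(
            f"event {event.value} is not legal in state {current.value}"
        ) from None
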