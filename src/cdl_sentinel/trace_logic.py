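"""Finite-trace temporal checks over simulation logs.

The simulator records a single path per run, so properties are evaluated
with finite-trace (LTLf-style) semantics: ``G p`` holds iff ``p`` holds at
every tick of the trace, ``F p`` iff it holds at at least one tick.  The
module also checks the ask/tell communication discipline (every ask is
eventually answered by a matching tell, unless the asked agent holds a
standing tell rule) and the two-level danger calculus: detecting one
triggering state formula raises a high (H) danger level, detecting both
raises it to severe (S).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Optional, Sequence

__all__ = [
    "DangerLevel",
    "PairingReport",
    "TraceEvent",
    "TraceProposition",
    "check_ask_tell_pairing",
    "danger_level",
    "group_by_tick",
    "holds_eventually",
    "holds_globally",
    "validate_trace",
]


@dataclass(frozen=True)
class TraceEvent:
    """One recorded event: ``kind`` is observation|message|alert|flag|monitoring."""

    tick: int
    kind: str
    payload: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tick < 0:
            raise ValueError("event tick must be >= 0")
        object.__setattr__(self, "payload", dict(self.payload))

    def as_dict(self) -> dict:
        return {"tick": self.tick, "kind": self.kind, "payload": dict(self.payload)}


Trace = Sequence[TraceEvent]


def validate_trace(trace: Trace) -> None:
    """Ticks must be non-decreasing."""
    last = -1
    for event in trace:
        if event.tick < last:
            raise ValueError(
                f"trace ticks decrease at tick {event.tick} (after {last})"
            )
        last = event.tick


@dataclass(frozen=True)
class TraceProposition:
    """A total predicate over one tick-state (the events sharing a tick)."""

    label: str
    predicate: Callable[[int, tuple[TraceEvent, ...]], bool]

    def __call__(self, tick: int, events: tuple[TraceEvent, ...]) -> bool:
        return bool(self.predicate(tick, events))

    def negate(self) -> "TraceProposition":
        return TraceProposition(
            f"not({self.label})", lambda t, ev: not self.predicate(t, ev)
        )


def group_by_tick(trace: Trace) -> list[tuple[int, tuple[TraceEvent, ...]]]:
    grouped: dict[int, list[TraceEvent]] = {}
    for event in trace:
        grouped.setdefault(event.tick, []).append(event)
    return [(t, tuple(grouped[t])) for t in sorted(grouped)]


def holds_globally(trace: Trace, prop: TraceProposition) -> bool:
    """Finite-trace G: vacuously true on the empty trace."""
    return all(prop(t, ev) for t, ev in group_by_tick(trace))


def holds_eventually(trace: Trace, prop: TraceProposition) -> bool:
    """Finite-trace F: false on the empty trace."""
    return any(prop(t, ev) for t, ev in group_by_tick(trace))


@dataclass(frozen=True)
class PairingReport:
    matched: tuple[TraceEvent, ...]
    unmatched: tuple[TraceEvent, ...]

    @property
    def ok(self) -> bool:
        return not self.unmatched


def check_ask_tell_pairing(
    trace: Trace,
    standing_tells: Iterable[tuple[str, str]] = (),
) -> PairingReport:
    """Pair each ask(j -> i, content) with a later-or-same-tick
    tell(i -> j, content); ``standing_tells`` lists (agent, content) pairs
    for which the asked agent holds a standing tell rule, which also counts
    as answered."""
    standing = set(standing_tells)
    messages = [e for e in trace if e.kind == "message"]
    matched: list[TraceEvent] = []
    unmatched: list[TraceEvent] = []
    for i, ask in enumerate(messages):
        if ask.payload.get("performative") != "ask":
            continue
        asked_agent = ask.payload.get("receiver")
        content = ask.payload.get("content")
        if (asked_agent, content) in standing:
            matched.append(ask)
            continue
        answered = any(
            reply.payload.get("performative") == "tell"
            and reply.payload.get("sender") == asked_agent
            and reply.payload.get("receiver") == ask.payload.get("sender")
            and reply.payload.get("content") == content
            and reply.tick >= ask.tick
            for reply in messages[i + 1 :]
        )
        (matched if answered else unmatched).append(ask)
    return PairingReport(tuple(matched), tuple(unmatched))


class DangerLevel(str, enum.Enum):
    HIGH = "H"
    SEVERE = "S"


def danger_level(
    phi_detected: bool, psi_detected: bool
) -> Optional[DangerLevel]:
    """H when exactly one triggering formula is detected, S when both,
    none when neither."""
    if phi_detected and psi_detected:
        return DangerLevel.SEVERE
    if phi_detected or psi_detected:
        return DangerLevel.HIGH
    return None
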