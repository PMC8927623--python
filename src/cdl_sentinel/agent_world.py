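"""Agent-based monitoring layer.

Sensor agents watch one signal each and raise an alert message to the
controller whenever a reading falls strictly outside the agent's normal
range (boundary values are normal).  The controller then runs the two-part
monitoring algorithm: collect contextual information every tick; when the
rule instances fired at a tick conflict, build the conflicting-rule set
(CRS), select its unique highest-priority member — patient-care (PC) agents
outrank environmental (Env) agents at equal numeric priority, with the rule
id as final lexicographic tie-break — and route the resulting alert to the
fixed authority list of the winning group.  A flag raised by an external
authority halts the whole system until an explicit reboot event.

Messages use a FIPA-style tell/ask/alert performative and a bracketed text
encoding mirroring the wire layout ``["Subject" "sender:…" "content:" "…"
"receiver:…"]``.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .rule_engine import Literal
from .sensor_synth import SensorReading
from .trace_logic import DangerLevel, TraceEvent, danger_level

__all__ = [
    "AgentGroup",
    "AlertEvent",
    "ConflictRuleSet",
    "Flag",
    "Message",
    "MessageError",
    "Performative",
    "RuleInstance",
    "Severity",
    "SensorAgent",
    "World",
    "WorldState",
    "build_crs",
    "decode_message",
    "encode_message",
    "observe",
    "reboot",
    "route_alert",
    "run_tick",
    "select_rule",
    "step_flag",
    "CONTROLLER_ID",
    "ENV_AUTHORITIES",
    "PC_AUTHORITIES",
]

CONTROLLER_ID = "controller"

PC_AUTHORITIES: tuple[str, ...] = ("doctor", "caretaker", "next_of_kin")
ENV_AUTHORITIES: tuple[str, ...] = (
    "fire_department",
    "emergency_response_unit",
    "police_department",
)


class AgentGroup(str, enum.Enum):
    PC = "PC_Agent"
    ENV = "Env_Agent"


class Performative(str, enum.Enum):
    TELL = "tell"
    ASK = "ask"
    ALERT = "alert"


class WorldState(str, enum.Enum):
    RUNNING = "RUNNING"
    HALTED = "HALTED"


class Severity(str, enum.Enum):
    NORMAL = "normal"
    HIGH = "high"
    SEVERE = "severe"


@dataclass(frozen=True)
class Flag:
    value: int = 0

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError("flag value must be 0 or 1")


@dataclass(frozen=True)
class SensorAgent:
    """One monitoring agent bound to a sensor kind and a normal range."""

    id: str
    sensor: str
    group: AgentGroup
    normal_range: tuple[float, float]
    context_id: str
    unit: str
    alert_head: Literal = Literal("emergency")
    alert_priority: int = 1
    alert_rule_id: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.normal_range
        if lo > hi:
            raise ValueError(f"agent {self.id!r}: normal range lo > hi")
        if not isinstance(self.group, AgentGroup):
            object.__setattr__(self, "group", AgentGroup(self.group))
        if not self.alert_rule_id:
            object.__setattr__(self, "alert_rule_id", f"alert_{self.id}")


@dataclass(frozen=True)
class Message:
    performative: Performative
    sender: str
    receiver: str
    content: str
    tick: int

    def __post_init__(self) -> None:
        if self.sender == self.receiver:
            raise ValueError("message sender and receiver must differ")
        if self.tick < 0:
            raise ValueError("message tick must be >= 0")
        if not isinstance(self.performative, Performative):
            object.__setattr__(
                self, "performative", Performative(self.performative)
            )


@dataclass(frozen=True)
class RuleInstance:
    """A rule that fired at some tick, as seen by the controller."""

    rule_id: str
    group: AgentGroup
    priority: int
    head: Literal
    agent_id: str = ""


@dataclass(frozen=True)
class ConflictRuleSet:
    """CRS: the mutually conflicting rule instances fired at one tick."""

    members: tuple[RuleInstance, ...]
    tick: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("conflict rule set must be non-empty")


@dataclass(frozen=True)
class AlertEvent:
    tick: int
    source: str
    literal: Literal
    severity: Severity
    route: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.route:
            raise ValueError("alert route must be non-empty")


@dataclass
class World:
    """Mutable simulation state: agents, run state, flag and the trace."""

    agents: dict[str, SensorAgent]
    state: WorldState = WorldState.RUNNING
    flag: Flag = Flag(0)
    trace: list[TraceEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Observation


def observe(agent: SensorAgent, reading: SensorReading) -> Optional[Message]:
    """Alert message to the controller iff the reading falls strictly
    outside the agent's normal range; boundary values are normal."""
    if reading.sensor != agent.sensor:
        raise ValueError(
            f"agent {agent.id!r} monitors {agent.sensor!r}, got a "
            f"{reading.sensor!r} reading"
        )
    if reading.unit != agent.unit:
        raise ValueError(
            f"agent {agent.id!r}: unit mismatch ({reading.unit!r} != "
            f"{agent.unit!r})"
        )
    if not math.isfinite(reading.value):
        raise ValueError(f"agent {agent.id!r}: non-finite reading")
    lo, hi = agent.normal_range
    if lo <= reading.value <= hi:
        return None
    label = agent.sensor.replace("_", " ").title()
    return Message(
        performative=Performative.ALERT,
        sender=agent.id,
        receiver=CONTROLLER_ID,
        content=f"Abnormal {label} Detected",
        tick=reading.tick,
    )


# ---------------------------------------------------------------------------
# Conflicting-rule-set algorithm


def _conflicts(a: RuleInstance, b: RuleInstance) -> bool:
    return a.head == b.head.complement()


def build_crs(
    fired: Sequence[RuleInstance], tick: int
) -> Optional[ConflictRuleSet]:
    """The CRS of a tick: every fired instance that conflicts with at least
    one other.  None when at most one rule fired or no pair conflicts."""
    if len(fired) <= 1:
        return None
    members = tuple(
        inst
        for inst in fired
        if any(_conflicts(inst, other) for other in fired if other is not inst)
    )
    if not members:
        return None
    return ConflictRuleSet(members, tick)


def _selection_key(inst: RuleInstance) -> tuple:
    return (
        -inst.priority,
        0 if inst.group is AgentGroup.PC else 1,
        inst.rule_id,
    )


def select_rule(crs: ConflictRuleSet) -> RuleInstance:
    """Unique maximum of the CRS under: priority desc, PC before Env,
    lexicographic rule id.  Permutation-invariant."""
    if not crs.members:
        raise ValueError("cannot select from an empty conflict rule set")
    return min(crs.members, key=_selection_key)


def route_alert(instance: RuleInstance) -> tuple[str, ...]:
    if instance.group is AgentGroup.PC:
        return PC_AUTHORITIES
    if instance.group is AgentGroup.ENV:
        return ENV_AUTHORITIES
    raise ValueError(f"unknown agent group {instance.group!r}")


# ---------------------------------------------------------------------------
# Flag semantics


def step_flag(flag: Flag, world: World) -> WorldState:
    """flag=1: authorities have taken over, the system halts; flag=0: keep
    gathering contextual information."""
    world.flag = flag
    world.state = WorldState.HALTED if flag.value == 1 else WorldState.RUNNING
    return world.state


def reboot(world: World) -> None:
    """Authority reboot: resume running with cleared flag/CRS state."""
    world.flag = Flag(0)
    world.state = WorldState.RUNNING


# ---------------------------------------------------------------------------
# Message codec

_SUBJECTS = {
    Performative.ALERT: "Emergency Situation",
    Performative.TELL: "Information Sharing",
    Performative.ASK: "Information Request",
}
_SUBJECT_TO_PERF = {v: k for k, v in _SUBJECTS.items()}

_MESSAGE_RE = re.compile(
    r'^\["(?P<subject>[^"]*)" "sender:(?P<sender>[^"]*)" "content:" '
    r'"(?P<content>[^"]*)" "receiver:(?P<receiver>[^"]*)" '
    r'"tick:(?P<tick>\d+)"\.\]$'
)


class MessageError(ValueError):
    """Malformed message string or unencodable field."""


def encode_message(msg: Message) -> str:
    for name, value in (
        ("sender", msg.sender),
        ("receiver", msg.receiver),
        ("content", msg.content),
    ):
        if '"' in value:
            raise MessageError(f"message {name} may not contain double quotes")
    subject = _SUBJECTS[msg.performative]
    return (
        f'["{subject}" "sender:{msg.sender}" "content:" "{msg.content}" '
        f'"receiver:{msg.receiver}" "tick:{msg.tick}".]'
    )


def decode_message(text: str) -> Message:
    match = _MESSAGE_RE.match(text.strip())
    if match is None:
        raise MessageError(f"malformed message string: {text!r}")
    subject = match.group("subject")
    if subject not in _SUBJECT_TO_PERF:
        raise MessageError(f"unknown message subject {subject!r}")
    return Message(
        performative=_SUBJECT_TO_PERF[subject],
        sender=match.group("sender"),
        receiver=match.group("receiver"),
        content=match.group("content"),
        tick=int(match.group("tick")),
    )


# ---------------------------------------------------------------------------
# Tick loop


def _severity(fired: Sequence[RuleInstance]) -> Severity:
    level = danger_level(
        any(inst.group is AgentGroup.PC for inst in fired),
        any(inst.group is AgentGroup.ENV for inst in fired),
    )
    if level is DangerLevel.SEVERE:
        return Severity.SEVERE
    if level is DangerLevel.HIGH:
        return Severity.HIGH
    return Severity.NORMAL


def run_tick(
    world: World, readings: Iterable[SensorReading], tick: int
) -> tuple[list[Message], list[AlertEvent], list[TraceEvent]]:
    """Process one tick: observe every reading (agent-id order), forward
    alert messages to the controller, build the CRS if fired instances
    conflict, select and route.  No-op while the world is halted."""
    if world.state is WorldState.HALTED:
        return [], [], []

    by_sensor: dict[str, list[SensorReading]] = {}
    for reading in readings:
        by_sensor.setdefault(reading.sensor, []).append(reading)

    events: list[TraceEvent] = [
        TraceEvent(tick, "monitoring", {"status": "Continuously Monitoring"})
    ]
    messages: list[Message] = []
    fired: list[RuleInstance] = []
    for agent_id in sorted(world.agents):
        agent = world.agents[agent_id]
        for reading in by_sensor.get(agent.sensor, ()):
            events.append(
                TraceEvent(
                    tick,
                    "observation",
                    {
                        "agent": agent.id,
                        "sensor": reading.sensor,
                        "value": reading.value,
                        "unit": reading.unit,
                    },
                )
            )
            msg = observe(agent, reading)
            if msg is None:
                continue
            messages.append(msg)
            events.append(
                TraceEvent(
                    tick,
                    "message",
                    {
                        "performative": msg.performative.value,
                        "sender": msg.sender,
                        "receiver": msg.receiver,
                        "content": msg.content,
                    },
                )
            )
            fired.append(
                RuleInstance(
                    rule_id=agent.alert_rule_id,
                    group=agent.group,
                    priority=agent.alert_priority,
                    head=agent.alert_head,
                    agent_id=agent.id,
                )
            )

    severity = _severity(fired)
    alerts: list[AlertEvent] = []
    crs = build_crs(fired, tick)
    if crs is not None:
        chosen = select_rule(crs)
        alerts.append(
            AlertEvent(
                tick=tick,
                source=chosen.agent_id or chosen.rule_id,
                literal=chosen.head,
                severity=severity,
                route=route_alert(chosen),
            )
        )
    else:
        for inst in fired:
            alerts.append(
                AlertEvent(
                    tick=tick,
                    source=inst.agent_id or inst.rule_id,
                    literal=inst.head,
                    severity=severity,
                    route=route_alert(inst),
                )
            )
    for alert in alerts:
        events.append(
            TraceEvent(
                tick,
                "alert",
                {
                    "source": alert.source,
                    "literal": str(alert.literal),
                    "severity": alert.severity.value,
                    "route": list(alert.route),
                },
            )
        )
    world.trace.extend(events)
    return messages, alerts, events
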