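"""Multi-context system (MCS) with prioritized mapping rules.

An MCS is a set of named contexts, each owning a local defeasible theory,
linked by *mapping rules* (also called bridge rules): rules whose bodies
reference literals owned by other contexts and whose head is local to the
owning context.  Mapping rules are always evaluated as *defeasible* rules —
imported knowledge must remain defeatable so that contextual defeasible
conflict resolution can arbitrate contradictory imports via the rules'
integer priorities.

Distributed queries resolve local literals with the local proof engine and
foreign body literals by recursive queries to their contexts, carrying a
call history so cyclic mapping graphs terminate: a cyclically dependent
branch evaluates as unprovable and taints the answer ``undefined`` when the
query could not otherwise be settled positively.

``equilibrium_check`` reports a context as inconsistent both when its
distributed conclusions contain a defeasibly-proved complementary pair
(possible only through an inconsistent strict part) and when complementary
literals each have applicable support but *neither* is concluded — the
deadlock a monitoring system cannot act on, which prioritized mappings are
there to break.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .rule_engine import (
    Literal,
    ProofTag,
    Rule,
    RuleKind,
    Theory,
    all_conclusions,
    conflicting_literals,
    prove,
)

__all__ = [
    "AnswerValue",
    "Context",
    "MCS",
    "MCSError",
    "MappingRule",
    "QueryAnswer",
    "build_mcs",
    "distributed_query",
    "equilibrium_check",
    "resolve_mapping_conflict",
]


class MCSError(ValueError):
    """Invalid multi-context system or query."""


@dataclass(frozen=True)
class Context:
    """A named knowledge source: local theory plus a trust rank
    (lower rank = more trusted, used only for deterministic tie-breaks)."""

    id: str
    theory: Theory
    preference_rank: int = 0


@dataclass(frozen=True)
class MappingRule:
    id: str
    owner: str
    body: frozenset[tuple[str, Literal]]
    head: Literal
    priority: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.body, frozenset):
            object.__setattr__(self, "body", frozenset(self.body))


@dataclass(frozen=True)
class MCS:
    contexts: Mapping[str, Context]
    mappings: Mapping[str, tuple[MappingRule, ...]]  # keyed by owner

    def dependency_graph(self) -> nx.DiGraph:
        """Directed graph: owner context -> context it imports from."""
        graph = nx.DiGraph()
        graph.add_nodes_from(self.contexts)
        for owner, rules in self.mappings.items():
            for rule in rules:
                for ctx_id, _ in rule.body:
                    graph.add_edge(owner, ctx_id)
        return graph


class AnswerValue(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class QueryAnswer:
    value: AnswerValue
    support: tuple[tuple[str, str], ...] = ()  # (context-id, rule-id) pairs


def build_mcs(
    contexts: Iterable[Context], mappings: Iterable[MappingRule] = ()
) -> MCS:
    ctx_map: dict[str, Context] = {}
    for ctx in contexts:
        if ctx.id in ctx_map:
            raise MCSError(f"duplicate context id {ctx.id!r}")
        ctx_map[ctx.id] = ctx
    grouped: dict[str, list[MappingRule]] = {cid: [] for cid in ctx_map}
    seen_ids: set[str] = set()
    for rule in mappings:
        if rule.owner not in ctx_map:
            raise MCSError(
                f"mapping {rule.id!r} owned by unknown context {rule.owner!r}"
            )
        for ctx_id, _ in rule.body:
            if ctx_id not in ctx_map:
                raise MCSError(
                    f"mapping {rule.id!r} references unknown context {ctx_id!r}"
                )
        if rule.id in seen_ids:
            raise MCSError(f"duplicate mapping id {rule.id!r}")
        local_ids = {r.id for r in ctx_map[rule.owner].theory.rules}
        if rule.id in local_ids:
            raise MCSError(
                f"mapping id {rule.id!r} clashes with a rule of context "
                f"{rule.owner!r}"
            )
        seen_ids.add(rule.id)
        grouped[rule.owner].append(rule)
    mcs = MCS(
        contexts=dict(ctx_map),
        mappings={k: tuple(v) for k, v in grouped.items()},
    )
    mcs.dependency_graph()  # must be computable
    return mcs


def _fired_mappings(
    mcs: MCS, context_id: str, history: frozenset
) -> tuple[list[MappingRule], dict[str, list[tuple[str, str]]], bool]:
    """Evaluate the context's mapping bodies by recursive distributed
    queries; return (fired rules, per-mapping foreign support,
    cycle-taint flag)."""
    fired: list[MappingRule] = []
    support: dict[str, list[tuple[str, str]]] = {}
    tainted = False
    for mapping in sorted(
        mcs.mappings.get(context_id, ()), key=lambda m: m.id
    ):
        body_ok = True
        body_support: list[tuple[str, str]] = []
        for ctx_id, lit in sorted(
            mapping.body, key=lambda pair: (pair[0], str(pair[1]))
        ):
            answer = distributed_query(mcs, ctx_id, lit, _history=history)
            if answer.value is AnswerValue.UNDEFINED:
                tainted = True
            if answer.value is not AnswerValue.POSITIVE:
                body_ok = False
                break
            body_support.extend(answer.support)
        if body_ok:
            fired.append(mapping)
            support[mapping.id] = body_support
    return fired, support, tainted


def _augment(theory: Theory, fired: Sequence[MappingRule]) -> Theory:
    """Local theory extended with each fired mapping as an empty-body
    defeasible rule carrying the mapping's priority."""
    extra = tuple(
        Rule(m.id, RuleKind.DEFEASIBLE, frozenset(), m.head, m.priority)
        for m in fired
    )
    return Theory(theory.facts, theory.rules + extra, theory.superiority)


def distributed_query(
    mcs: MCS,
    context_id: str,
    literal: Literal,
    *,
    _history: frozenset = frozenset(),
) -> QueryAnswer:
    """Defeasible provability of ``literal`` in ``context_id`` given all
    imports the mapping rules can justify.

    Terminates on every MCS: the call history bounds recursion by
    |contexts| x |literals| and a revisited (context, literal) pair is cut
    off as unprovable.
    """
    if context_id not in mcs.contexts:
        raise MCSError(f"unknown context {context_id!r}")
    key = (context_id, literal)
    if key in _history:
        return QueryAnswer(AnswerValue.UNDEFINED)
    history = _history | {key}
    context = mcs.contexts[context_id]
    fired, foreign_support, tainted = _fired_mappings(mcs, context_id, history)
    theory = _augment(context.theory, fired)
    if prove(theory, literal, ProofTag.POS_DEFEASIBLE):
        concl = all_conclusions(theory)
        proved = {
            c.literal for c in concl if c.tag is ProofTag.POS_DEFEASIBLE
        }
        support = [
            (context_id, r.id)
            for r in theory.rules
            if r.head == literal
            and r.kind is not RuleKind.DEFEATER
            and r.body <= proved
        ]
        for mapping in fired:
            if mapping.head == literal:
                support.extend(foreign_support.get(mapping.id, ()))
        return QueryAnswer(AnswerValue.POSITIVE, tuple(sorted(set(support))))
    value = AnswerValue.UNDEFINED if tainted else AnswerValue.NEGATIVE
    return QueryAnswer(value)


def resolve_mapping_conflict(
    candidates: Sequence[tuple[MappingRule, QueryAnswer]],
    ranks: Optional[Mapping[str, int]] = None,
) -> MappingRule:
    """Pick the mapping rule that wins a conflict among candidates with
    complementary heads: highest priority, then most-trusted owner
    (lowest preference rank), then lexicographically smallest rule id."""
    if not candidates:
        raise MCSError("resolve_mapping_conflict: empty candidate list")
    ranks = ranks or {}

    def sort_key(item: tuple[MappingRule, QueryAnswer]):
        rule, _ = item
        return (-rule.priority, ranks.get(rule.owner, 0), rule.id)

    return min(candidates, key=sort_key)[0]


def equilibrium_check(mcs: MCS) -> tuple[bool, list[tuple[str, str]]]:
    """System-wide consistency: every context's distributed conclusions are
    conflict-free and every import conflict is actually resolved.

    Returns ``(in_equilibrium, report)`` where the report lists
    ``(context-id, atom)`` pairs.
    """
    report: list[tuple[str, str]] = []
    for ctx_id in sorted(mcs.contexts):
        context = mcs.contexts[ctx_id]
        fired, _, _ = _fired_mappings(mcs, ctx_id, frozenset())
        theory = _augment(context.theory, fired)
        concl = all_conclusions(theory)
        proved = {
            c.literal for c in concl if c.tag is ProofTag.POS_DEFEASIBLE
        }
        for atom in sorted(conflicting_literals(concl)):
            report.append((ctx_id, atom))

        # Deadlocks: complementary applicable support, neither sign concluded.
        supportive = [
            r for r in theory.rules if r.kind is not RuleKind.DEFEATER
        ]
        applicable_heads = {
            r.head for r in supportive if r.body <= proved
        } | theory.facts
        for lit in sorted(applicable_heads, key=lambda l: (l.atom, l.negated)):
            if lit.negated:
                continue
            comp = lit.complement()
            if comp not in applicable_heads:
                continue
            if lit not in proved and comp not in proved:
                if (ctx_id, lit.atom) not in report:
                    report.append((ctx_id, lit.atom))
    return (not report, report)
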