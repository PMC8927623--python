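"""Propositional defeasible-logic proof kernel.

Theories consist of facts, strict rules, defeasible rules, defeaters and a
superiority relation.  Conclusions are tagged:

* ``+Δ`` / ``-Δ`` — definitely provable / definitely refutable, using facts
  and strict rules only (monotonic part).
* ``+∂`` / ``-∂`` — defeasibly provable / defeasibly refutable, where a
  defeasible conclusion stands only if every rule for the complementary
  literal is either inapplicable or defeated by a superior supporting rule.

The semantics is the standard ambiguity-blocking variant *with team defeat*:
an attacking rule may be beaten by any applicable supporting rule, not only
the one currently being used.  Superiority between two conflicting rules is
decided by an explicit superiority pair when one exists, otherwise by the
rules' integer priorities (higher wins); equal priority and no pair means
neither defeats the other, so both conclusions are skeptically withheld.

Negation is strong negation only (``~p``); rule bodies contain no
negation-as-failure.  Conclusions are computed bottom-up as the least
fixpoint of the proof conditions, which terminates on every finite theory
and automatically satisfies coherence (never ``+∂p`` and ``-∂p`` together).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Union

import networkx as nx
import yaml

__all__ = [
    "Literal",
    "ProofTag",
    "Rule",
    "RuleKind",
    "TaggedConclusion",
    "Theory",
    "TheoryError",
    "all_conclusions",
    "conflicting_literals",
    "parse_theory",
    "prove",
]


class TheoryError(ValueError):
    """Invalid or unparsable defeasible theory."""


@dataclass(frozen=True, order=True)
class Literal:
    """An atom or its strong negation (``~atom``)."""

    atom: str
    negated: bool = False

    def __post_init__(self) -> None:
        if not self.atom or not isinstance(self.atom, str):
            raise TheoryError("literal atom must be a non-empty string")

    @classmethod
    def parse(cls, text: str) -> "Literal":
        text = str(text).strip()
        if text.startswith("~"):
            return cls(text[1:].strip(), True)
        return cls(text, False)

    def complement(self) -> "Literal":
        return Literal(self.atom, not self.negated)

    def __str__(self) -> str:
        return f"~{self.atom}" if self.negated else self.atom


class RuleKind(str, enum.Enum):
    STRICT = "strict"
    DEFEASIBLE = "defeasible"
    DEFEATER = "defeater"


class ProofTag(str, enum.Enum):
    """Proof tags: +Δ, -Δ, +∂, -∂."""

    POS_DEFINITE = "+D"
    NEG_DEFINITE = "-D"
    POS_DEFEASIBLE = "+d"
    NEG_DEFEASIBLE = "-d"


@dataclass(frozen=True)
class Rule:
    id: str
    kind: RuleKind
    body: frozenset[Literal]
    head: Literal
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise TheoryError("rule id must be non-empty")
        if not isinstance(self.kind, RuleKind):
            object.__setattr__(self, "kind", RuleKind(self.kind))
        if not isinstance(self.body, frozenset):
            object.__setattr__(self, "body", frozenset(self.body))
        if self.priority < 0:
            raise TheoryError(f"rule {self.id!r}: priority must be >= 0")


@dataclass(frozen=True)
class TaggedConclusion:
    literal: Literal
    tag: ProofTag


@dataclass(frozen=True)
class Theory:
    """Facts, rules and a superiority relation over conflicting rules.

    ``superiority`` pairs ``(winner, loser)`` may only relate rules with
    complementary heads and must be irreflexive and acyclic.
    """

    facts: frozenset[Literal] = frozenset()
    rules: tuple[Rule, ...] = ()
    superiority: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if not isinstance(self.facts, frozenset):
            object.__setattr__(self, "facts", frozenset(self.facts))
        if not isinstance(self.rules, tuple):
            object.__setattr__(self, "rules", tuple(self.rules))
        if not isinstance(self.superiority, frozenset):
            object.__setattr__(self, "superiority", frozenset(self.superiority))
        by_id: dict[str, Rule] = {}
        for rule in self.rules:
            if rule.id in by_id:
                raise TheoryError(f"duplicate rule id {rule.id!r}")
            by_id[rule.id] = rule
        for winner, loser in self.superiority:
            if winner == loser:
                raise TheoryError(f"superiority is reflexive on {winner!r}")
            for rid in (winner, loser):
                if rid not in by_id:
                    raise TheoryError(f"superiority references unknown rule {rid!r}")
            if by_id[winner].head != by_id[loser].head.complement():
                raise TheoryError(
                    f"superiority {winner!r} > {loser!r} relates rules whose heads "
                    "are not complementary"
                )
        graph = nx.DiGraph(self.superiority)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise TheoryError(f"superiority relation is cyclic: {cycle}")

    # -- structural helpers -------------------------------------------------

    def rule(self, rule_id: str) -> Rule:
        for r in self.rules:
            if r.id == rule_id:
                return r
        raise KeyError(rule_id)

    def atoms(self) -> tuple[str, ...]:
        seen: set[str] = {lit.atom for lit in self.facts}
        for rule in self.rules:
            seen.add(rule.head.atom)
            seen.update(lit.atom for lit in rule.body)
        return tuple(sorted(seen))

    def literals(self) -> tuple[Literal, ...]:
        return tuple(
            Literal(a, neg) for a in self.atoms() for neg in (False, True)
        )

    def beats(self, winner: Rule, loser: Rule) -> bool:
        """True iff ``winner`` is superior to ``loser``.

        An explicit superiority pair overrides numeric priorities; with no
        pair either way, the higher integer priority wins.
        """
        if (winner.id, loser.id) in self.superiority:
            return True
        if (loser.id, winner.id) in self.superiority:
            return False
        return winner.priority > loser.priority


# ---------------------------------------------------------------------------
# Parsing


def parse_theory(source: str) -> Theory:
    """Parse the YAML theory dialect into a validated :class:`Theory`.

    Grammar: top-level mapping with optional keys ``facts`` (list of literal
    strings, ``~`` prefix for strong negation), ``rules`` (list of mappings
    with ``id``, ``kind`` in strict|defeasible|defeater, ``body`` list,
    ``head``, integer ``priority``) and ``superiority`` (list of
    ``"id > id"`` strings).
    """
    try:
        data = yaml.safe_load(source)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = mark.line + 1 if mark is not None else "?"
        raise TheoryError(f"theory syntax error at line {line}: {exc}") from exc
    if data is None:
        return Theory()
    return theory_from_mapping(data)


def theory_from_mapping(data: object) -> Theory:
    """Build a :class:`Theory` from an already-deserialized mapping."""
    if not isinstance(data, dict):
        raise TheoryError("theory document must be a mapping")
    unknown = set(data) - {"facts", "rules", "superiority"}
    if unknown:
        raise TheoryError(f"unknown theory keys: {sorted(unknown)}")
    facts = frozenset(Literal.parse(f) for f in data.get("facts") or [])
    rules = []
    for i, raw in enumerate(data.get("rules") or []):
        if not isinstance(raw, dict) or "id" not in raw or "head" not in raw:
            raise TheoryError(f"rule #{i + 1} must be a mapping with id and head")
        try:
            kind = RuleKind(str(raw.get("kind", "defeasible")))
        except ValueError as exc:
            raise TheoryError(
                f"rule {raw['id']!r}: unknown kind {raw.get('kind')!r}"
            ) from exc
        rules.append(
            Rule(
                id=str(raw["id"]),
                kind=kind,
                body=frozenset(Literal.parse(b) for b in raw.get("body") or []),
                head=Literal.parse(raw["head"]),
                priority=int(raw.get("priority", 0)),
            )
        )
    superiority = []
    for entry in data.get("superiority") or []:
        parts = str(entry).split(">")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise TheoryError(
                f"superiority entry {entry!r} must have the form 'winner > loser'"
            )
        superiority.append((parts[0].strip(), parts[1].strip()))
    return Theory(facts, tuple(rules), frozenset(superiority))


# ---------------------------------------------------------------------------
# Proof conditions (bottom-up least fixpoint)


@lru_cache(maxsize=512)
def _closure(theory: Theory) -> frozenset[TaggedConclusion]:
    lits = theory.literals()
    strict_for: dict[Literal, list[Rule]] = {q: [] for q in lits}
    supportive_for: dict[Literal, list[Rule]] = {q: [] for q in lits}
    any_for: dict[Literal, list[Rule]] = {q: [] for q in lits}
    for rule in theory.rules:
        any_for[rule.head].append(rule)
        if rule.kind is RuleKind.STRICT:
            strict_for[rule.head].append(rule)
        if rule.kind is not RuleKind.DEFEATER:
            supportive_for[rule.head].append(rule)

    # +Δ: facts, closed under strict rules.
    plus_delta: set[Literal] = set()
    changed = True
    while changed:
        changed = False
        for q in lits:
            if q in plus_delta:
                continue
            if q in theory.facts or any(
                r.body <= plus_delta for r in strict_for[q]
            ):
                plus_delta.add(q)
                changed = True

    # -Δ: provably not definitely derivable (least fixpoint; literals on a
    # strict cycle receive neither tag, which keeps coherence).
    minus_delta: set[Literal] = set()
    changed = True
    while changed:
        changed = False
        for q in lits:
            if q in minus_delta or q in theory.facts:
                continue
            if all(
                any(b in minus_delta for b in r.body) for r in strict_for[q]
            ):
                minus_delta.add(q)
                changed = True

    plus_par: set[Literal] = set()
    minus_par: set[Literal] = set()

    def supported(q: Literal) -> list[Rule]:
        return [r for r in supportive_for[q] if r.body <= plus_par]

    changed = True
    while changed:
        changed = False
        for q in lits:
            comp = q.complement()
            if q not in plus_par:
                derivable = False
                if q in plus_delta:
                    derivable = True
                elif comp in minus_delta:
                    team = supported(q)
                    if team and all(
                        any(b in minus_par for b in s.body)
                        or any(theory.beats(t, s) for t in team)
                        for s in any_for[comp]
                    ):
                        derivable = True
                if derivable:
                    plus_par.add(q)
                    changed = True
            if q not in minus_par and q in minus_delta:
                refuted = False
                if all(
                    any(b in minus_par for b in r.body) for r in supportive_for[q]
                ):
                    refuted = True
                elif comp in plus_delta:
                    refuted = True
                else:
                    for s in any_for[comp]:
                        if s.body <= plus_par and all(
                            any(b in minus_par for b in t.body)
                            or not theory.beats(t, s)
                            for t in supportive_for[q]
                        ):
                            refuted = True
                            break
                if refuted:
                    minus_par.add(q)
                    changed = True

    out: set[TaggedConclusion] = set()
    for q, tag_set in (
        (ProofTag.POS_DEFINITE, plus_delta),
        (ProofTag.NEG_DEFINITE, minus_delta),
        (ProofTag.POS_DEFEASIBLE, plus_par),
        (ProofTag.NEG_DEFEASIBLE, minus_par),
    ):
        out.update(TaggedConclusion(lit, q) for lit in tag_set)
    return frozenset(out)


def prove(theory: Theory, literal: Literal, tag: Union[ProofTag, str]) -> bool:
    """Decide whether ``literal`` carries proof ``tag`` in ``theory``.

    Total on valid input; a literal over an atom foreign to the theory is
    definitely and defeasibly refutable.
    """
    tag = ProofTag(tag)
    if literal.atom not in theory.atoms():
        return tag in (ProofTag.NEG_DEFINITE, ProofTag.NEG_DEFEASIBLE)
    return TaggedConclusion(literal, tag) in _closure(theory)


def all_conclusions(theory: Theory) -> frozenset[TaggedConclusion]:
    """All tagged conclusions over the atoms appearing in the theory."""
    return _closure(theory)


def conflicting_literals(
    conclusions: Iterable[TaggedConclusion],
) -> frozenset[str]:
    """Atoms defeasibly concluded with both signs (strict-part inconsistency)."""
    pos: set[str] = set()
    neg: set[str] = set()
    for concl in conclusions:
        if concl.tag is ProofTag.POS_DEFEASIBLE:
            (neg if concl.literal.negated else pos).add(concl.literal.atom)
    return frozenset(pos & neg)
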