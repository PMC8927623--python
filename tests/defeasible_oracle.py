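"""Independent top-down evaluator of the defeasible proof conditions.

Written as a direct recursive transcription of the inference conditions
(ambiguity blocking, team defeat) with a path-history loop check and no
memoization — deliberately a different algorithm from the package's
bottom-up fixpoint engine, so the two can cross-check each other.

Also hosts a seeded random-theory generator used by the equivalence and
property suites.
"""

from __future__ import annotations

import numpy as np

from cdl_sentinel.rule_engine import (
    Literal,
    ProofTag,
    Rule,
    RuleKind,
    TaggedConclusion,
    Theory,
)


def _supportive(theory: Theory, lit: Literal) -> list[Rule]:
    return [
        r
        for r in theory.rules
        if r.head == lit and r.kind is not RuleKind.DEFEATER
    ]


def _strict(theory: Theory, lit: Literal) -> list[Rule]:
    return [
        r for r in theory.rules if r.head == lit and r.kind is RuleKind.STRICT
    ]


def _any_rule(theory: Theory, lit: Literal) -> list[Rule]:
    return [r for r in theory.rules if r.head == lit]


def demonstrate(
    theory: Theory,
    literal: Literal,
    tag: ProofTag,
    _path: frozenset = frozenset(),
) -> bool:
    """Recursive proof search; a goal revisited on the current path fails."""
    key = (tag, literal)
    if key in _path:
        return False
    path = _path | {key}

    def demo(lit: Literal, t: ProofTag) -> bool:
        return demonstrate(theory, lit, t, path)

    comp = literal.complement()

    if tag is ProofTag.POS_DEFINITE:
        if literal in theory.facts:
            return True
        return any(
            all(demo(b, ProofTag.POS_DEFINITE) for b in r.body)
            for r in _strict(theory, literal)
        )

    if tag is ProofTag.NEG_DEFINITE:
        if literal in theory.facts:
            return False
        return all(
            any(demo(b, ProofTag.NEG_DEFINITE) for b in r.body)
            for r in _strict(theory, literal)
        )

    if tag is ProofTag.POS_DEFEASIBLE:
        if demo(literal, ProofTag.POS_DEFINITE):
            return True
        if not demo(comp, ProofTag.NEG_DEFINITE):
            return False
        team = _supportive(theory, literal)
        for r in team:
            if not all(demo(b, ProofTag.POS_DEFEASIBLE) for b in r.body):
                continue
            if all(
                any(demo(b, ProofTag.NEG_DEFEASIBLE) for b in s.body)
                or any(
                    all(demo(b, ProofTag.POS_DEFEASIBLE) for b in t.body)
                    and theory.beats(t, s)
                    for t in team
                )
                for s in _any_rule(theory, comp)
            ):
                return True
        return False

    if tag is ProofTag.NEG_DEFEASIBLE:
        if not demo(literal, ProofTag.NEG_DEFINITE):
            return False
        team = _supportive(theory, literal)
        if all(
            any(demo(b, ProofTag.NEG_DEFEASIBLE) for b in r.body) for r in team
        ):
            return True
        if demo(comp, ProofTag.POS_DEFINITE):
            return True
        for s in _any_rule(theory, comp):
            if all(demo(b, ProofTag.POS_DEFEASIBLE) for b in s.body) and all(
                any(demo(b, ProofTag.NEG_DEFEASIBLE) for b in t.body)
                or not theory.beats(t, s)
                for t in team
            ):
                return True
        return False

    raise ValueError(tag)


def oracle_conclusions(theory: Theory) -> frozenset[TaggedConclusion]:
    out = set()
    for lit in theory.literals():
        for tag in ProofTag:
            if demonstrate(theory, lit, tag):
                out.add(TaggedConclusion(lit, tag))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Seeded random theory generation

_ATOMS = "abcdef"
_KINDS = (RuleKind.STRICT, RuleKind.DEFEASIBLE, RuleKind.DEFEATER)


def random_theory(
    rng: np.random.Generator,
    max_rules: int = 10,
    max_atoms: int = 6,
) -> Theory:
    """Draw a small valid theory: random rules, facts and an acyclic
    superiority relation over complementary-headed rule pairs."""
    atoms = list(_ATOMS[: int(rng.integers(1, max_atoms + 1))])

    def lit() -> Literal:
        return Literal(str(rng.choice(atoms)), bool(rng.integers(2)))

    rules = []
    for i in range(int(rng.integers(0, max_rules + 1))):
        body = frozenset(lit() for _ in range(int(rng.integers(0, 3))))
        kind = _KINDS[int(rng.choice(3, p=[0.3, 0.55, 0.15]))]
        rules.append(
            Rule(f"r{i}", kind, body, lit(), priority=int(rng.integers(0, 4)))
        )
    facts = frozenset(lit() for _ in range(int(rng.integers(0, 3))))

    candidates = [
        (a.id, b.id)
        for a in rules
        for b in rules
        if a.id != b.id and a.head == b.head.complement()
    ]
    superiority: set[tuple[str, str]] = set()
    if candidates:
        rng.shuffle(candidates)
        for winner, loser in candidates[: int(rng.integers(0, 3))]:
            if (loser, winner) not in superiority:
                superiority.add((winner, loser))
    return Theory(facts, tuple(rules), frozenset(superiority))
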