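"""Defeasible-logic kernel: parsing, proof tags, invariants, oracle checks."""

import numpy as np
import pytest

from cdl_sentinel.rule_engine import (
    Literal,
    ProofTag,
    Rule,
    RuleKind,
    TaggedConclusion,
    Theory,
    TheoryError,
    all_conclusions,
    conflicting_literals,
    parse_theory,
    prove,
)
from defeasible_oracle import demonstrate, oracle_conclusions, random_theory

L = Literal.parse


def rule(rid, head, body=(), kind="defeasible", priority=0):
    return Rule(rid, RuleKind(kind), frozenset(map(L, body)), L(head), priority)


# ---------------------------------------------------------------------------
# Literals


def test_literal_complement_is_involutive():
    lit = L("~emergency")
    assert lit.negated and lit.atom == "emergency"
    assert lit.complement().complement() == lit
    assert str(lit) == "~emergency"


def test_empty_atom_rejected():
    with pytest.raises(TheoryError):
        Literal("")


# ---------------------------------------------------------------------------
# Parsing


def test_parse_empty_source_gives_empty_theory():
    theory = parse_theory("")
    assert theory.facts == frozenset() and theory.rules == ()


def test_parse_fact_and_defeasible_rule():
    theory = parse_theory(
        """
facts: [abnormal_bp]
rules:
  - {id: r1, kind: defeasible, body: [abnormal_bp], head: emergency}
"""
    )
    assert theory.facts == {L("abnormal_bp")}
    assert len(theory.rules) == 1
    assert theory.rules[0].head == L("emergency")


@pytest.mark.parametrize(
    "source, fragment",
    [
        ("facts: [p]\nrules: [{id: r1, head: q}, {id: r1, head: p}]", "duplicate"),
        (
            "rules: [{id: r1, head: q}, {id: r2, head: ~q}]\n"
            "superiority: ['r1 > r2', 'r2 > r1']",
            "cyclic",
        ),
        (
            # same-sign heads may not be related by superiority
            "rules: [{id: r1, head: emergency}, {id: r2, head: emergency}]\n"
            "superiority: ['r1 > r2']",
            "complementary",
        ),
        ("rules: [{id: r1, head: q}]\nsuperiority: ['r1 > ghost']", "unknown"),
        ("rules: [{id: r1, head: q, kind: maybe}]", "kind"),
        ("facts: [p", "syntax error at line"),
    ],
)
def test_parse_rejects_invalid_theories(source, fragment):
    with pytest.raises(TheoryError, match=fragment):
        parse_theory(source)


# ---------------------------------------------------------------------------
# Proof conditions


def test_facts_are_definitely_and_defeasibly_provable():
    theory = Theory(facts=frozenset({L("p")}))
    assert prove(theory, L("p"), ProofTag.POS_DEFINITE)
    assert prove(theory, L("p"), ProofTag.POS_DEFEASIBLE)


def test_unopposed_defeasible_rule_fires():
    theory = Theory(frozenset({L("p")}), (rule("r1", "q", ["p"]),))
    assert prove(theory, L("q"), ProofTag.POS_DEFEASIBLE)


def test_superiority_decides_between_conflicting_rules():
    theory = Theory(
        rules=(rule("r1", "q"), rule("r2", "~q")),
        superiority=frozenset({("r1", "r2")}),
    )
    assert prove(theory, L("q"), ProofTag.POS_DEFEASIBLE)
    assert not prove(theory, L("~q"), ProofTag.POS_DEFEASIBLE)
    # cross-checked against the independent recursive evaluator
    assert demonstrate(theory, L("q"), ProofTag.POS_DEFEASIBLE)
    assert not demonstrate(theory, L("~q"), ProofTag.POS_DEFEASIBLE)


def test_equal_priority_conflict_is_skeptical():
    theory = Theory(rules=(rule("r1", "q"), rule("r2", "~q")))
    assert not prove(theory, L("q"), ProofTag.POS_DEFEASIBLE)
    assert not prove(theory, L("~q"), ProofTag.POS_DEFEASIBLE)
    assert prove(theory, L("q"), ProofTag.NEG_DEFEASIBLE)


def test_numeric_priority_induces_superiority():
    theory = Theory(
        rules=(rule("r1", "q", priority=5), rule("r2", "~q", priority=2))
    )
    assert prove(theory, L("q"), ProofTag.POS_DEFEASIBLE)


def test_explicit_superiority_overrides_numeric_priority():
    theory = Theory(
        rules=(rule("r1", "q", priority=0), rule("r2", "~q", priority=9)),
        superiority=frozenset({("r1", "r2")}),
    )
    assert prove(theory, L("q"), ProofTag.POS_DEFEASIBLE)
    assert not prove(theory, L("~q"), ProofTag.POS_DEFEASIBLE)


def test_strict_chaining_and_team_defeat():
    theory = Theory(
        frozenset({L("p")}),
        (Rule("s1", RuleKind.STRICT, frozenset({L("p")}), L("q")),),
    )
    assert TaggedConclusion(L("q"), ProofTag.POS_DEFINITE) in all_conclusions(
        theory
    )
    # team defeat: the attacker is beaten by a supporter other than the
    # rule whose applicability carries the conclusion
    team = Theory(
        rules=(
            rule("a1", "q", priority=1),
            rule("a2", "q", priority=3),
            rule("b1", "~q", priority=2),
        )
    )
    assert prove(team, L("q"), ProofTag.POS_DEFEASIBLE)


def test_defeaters_block_but_never_support():
    theory = Theory(
        rules=(
            rule("d1", "q", kind="defeater", priority=5),
            rule("r1", "~q", priority=1),
        )
    )
    # the defeater blocks ~q but cannot establish q
    assert not prove(theory, L("~q"), ProofTag.POS_DEFEASIBLE)
    assert not prove(theory, L("q"), ProofTag.POS_DEFEASIBLE)


def test_cyclic_support_is_unprovable():
    # mutually dependent rules: the loop blocks the proof, so the literal
    # carries neither the positive nor the negative defeasible tag
    theory = Theory(rules=(rule("r1", "p", ["q"]), rule("r2", "q", ["p"])))
    assert not prove(theory, L("p"), ProofTag.POS_DEFEASIBLE)
    assert not prove(theory, L("p"), ProofTag.NEG_DEFEASIBLE)
    assert prove(theory, L("p"), ProofTag.NEG_DEFINITE)
    # and the engine agrees with the recursive evaluator on the whole theory
    assert all_conclusions(theory) == oracle_conclusions(theory)


def test_foreign_atom_is_refutable():
    theory = Theory(facts=frozenset({L("p")}))
    assert prove(theory, L("zzz"), ProofTag.NEG_DEFINITE)
    assert not prove(theory, L("zzz"), ProofTag.POS_DEFEASIBLE)


# ---------------------------------------------------------------------------
# Closure-level operations


def test_empty_theory_yields_only_negative_tags():
    concl = all_conclusions(Theory())
    assert concl == frozenset()
    theory = Theory(rules=(rule("r1", "q", ["p"]),))
    tags = {
        (str(c.literal), c.tag) for c in all_conclusions(theory)
    }
    assert ("p", ProofTag.POS_DEFINITE) not in tags
    assert ("p", ProofTag.NEG_DEFINITE) in tags
    assert ("q", ProofTag.NEG_DEFEASIBLE) in tags


def test_conflicting_literals_detects_strict_contradiction():
    theory = Theory(facts=frozenset({L("p"), L("~p")}))
    assert conflicting_literals(all_conclusions(theory)) == {"p"}
    assert conflicting_literals(frozenset()) == frozenset()


def test_consistent_strict_part_never_conflicts():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        theory = random_theory(rng)
        concl = all_conclusions(theory)
        strict_conflict = any(
            TaggedConclusion(Literal(a), ProofTag.POS_DEFINITE) in concl
            and TaggedConclusion(Literal(a, True), ProofTag.POS_DEFINITE)
            in concl
            for a in theory.atoms()
        )
        if not strict_conflict:
            assert conflicting_literals(concl) == frozenset()


# ---------------------------------------------------------------------------
# Engine-wide properties over random theories


def test_engine_matches_oracle_on_random_theories():
    rng = np.random.default_rng(424242)
    for _ in range(150):
        theory = random_theory(rng)
        assert all_conclusions(theory) == oracle_conclusions(theory)


def test_coherence_containment_and_monotone_facts():
    rng = np.random.default_rng(99)
    for _ in range(100):
        theory = random_theory(rng)
        concl = all_conclusions(theory)
        for lit in theory.literals():
            assert not (
                TaggedConclusion(lit, ProofTag.POS_DEFINITE) in concl
                and TaggedConclusion(lit, ProofTag.NEG_DEFINITE) in concl
            )
            assert not (
                TaggedConclusion(lit, ProofTag.POS_DEFEASIBLE) in concl
                and TaggedConclusion(lit, ProofTag.NEG_DEFEASIBLE) in concl
            )
            if TaggedConclusion(lit, ProofTag.POS_DEFINITE) in concl:
                assert TaggedConclusion(lit, ProofTag.POS_DEFEASIBLE) in concl
        # adding any fact makes it definitely provable
        new_fact = Literal("zz_new")
        extended = Theory(
            theory.facts | {new_fact}, theory.rules, theory.superiority
        )
        assert prove(extended, new_fact, ProofTag.POS_DEFINITE)


def test_defeater_only_support_is_inert():
    rng = np.random.default_rng(7)
    for _ in range(100):
        theory = random_theory(rng)
        concl = all_conclusions(theory)
        for lit in theory.literals():
            supporters = [
                r
                for r in theory.rules
                if r.head == lit and r.kind is not RuleKind.DEFEATER
            ]
            if lit not in theory.facts and not supporters:
                assert (
                    TaggedConclusion(lit, ProofTag.POS_DEFEASIBLE)
                    not in concl
                )


def test_no_conflict_theory_reduces_to_forward_chaining():
    rng = np.random.default_rng(31)
    checked = 0
    while checked < 50:
        theory = random_theory(rng)
        heads = {r.head for r in theory.rules} | theory.facts
        if any(h.complement() in heads for h in heads):
            continue
        if any(r.kind is RuleKind.DEFEATER for r in theory.rules):
            continue
        checked += 1
        closure = set(theory.facts)
        changed = True
        while changed:
            changed = False
            for r in theory.rules:
                if r.body <= closure and r.head not in closure:
                    closure.add(r.head)
                    changed = True
        concl = all_conclusions(theory)
        derived = {
            c.literal for c in concl if c.tag is ProofTag.POS_DEFEASIBLE
        }
        assert derived == closure
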