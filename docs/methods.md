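# Methods

## Defeasible-logic semantics

The proof kernel implements propositional, **ambiguity-blocking**
defeasible logic **with team defeat**.  For a theory `D = (F, R, >)` the
four tags are defined by the usual inference conditions:

* `+Δ p` — `p ∈ F`, or some strict rule for `p` has an all-`+Δ` body.
* `−Δ p` — `p ∉ F` and every strict rule for `p` has a `−Δ` body literal.
* `+∂ p` — `+Δ p`; or `−Δ ~p`, some supportive (strict or defeasible) rule
  for `p` is applicable (all body literals `+∂`), and every rule for `~p`
  is either discarded (some body literal `−∂`) or defeated by **some**
  applicable supportive rule for `p` that is superior to it (team defeat).
* `−∂ p` — the constructive failure of the above.

These conditions are positive-inductive over tagged literals, so the
engine computes their joint **least fixpoint bottom-up**; that guarantees
termination on every finite theory and makes coherence (`+∂p` and `−∂p`
never both hold; likewise for `Δ`) a structural property rather than a
checked one.  A literal whose support is cyclic (e.g. `q ⇒ p`, `p ⇒ q`)
receives *neither* the positive nor the negative defeasible tag: the loop
blocks both proofs.  This matches a top-down prover with an "in-progress"
marker, and the test suite cross-checks the fixpoint engine against an
independently written recursive evaluator with a path-history loop check
on hundreds of seeded random theories.

Two provenances of superiority coexist: integer rule priorities (higher
wins) induce superiority between any pair of conflicting rules, while an
explicit `winner > loser` pair overrides the numeric comparison for that
pair.  Equal priority with no explicit pair means neither rule defeats the
other, so both conclusions are skeptically withheld.  Negation is strong
negation only; `+∂p` together with `+∂¬p` is possible only through an
inconsistent strict part (e.g. contradictory facts), which is exactly what
`conflicting_literals` detects.

## Multi-context semantics

Mapping rules are evaluated as *defeasible* rules: when a mapping's
foreign body literals are all answered positively by their home contexts,
the mapping joins the owner's theory as an empty-body defeasible rule
carrying the mapping's priority.  Imported knowledge therefore competes
with local rules and other imports under exactly the same defeat
machinery.

**Cycles.** Distributed queries carry a `(context, literal)` call history;
a revisited pair evaluates as unprovable on that branch.  If the final
answer is positive it stands on its own support and is reported
`positive`; if the query fails after a cycle was cut anywhere in its
evaluation the answer is reported `undefined` (the cut *may* have decided
it), otherwise `negative`.  This makes the query a total, terminating
function with at most `|contexts| x |literals|` recursive frames.

**Equilibrium.** A context is flagged inconsistent when (a) its
distributed conclusions contain a defeasibly proved complementary pair, or
(b) complementary literals each have applicable support (local rule, fact
or fired mapping) but *neither* sign is concluded.  Case (b) is the
deadlock of two equal-strength opposing voices: the system cannot derive a
decision, which for a safety-critical monitor is a failure state, and it
is precisely the state that assigning priorities to mapping rules is meant
to eliminate.  A skeptical reading that only checked (a) would label the
deadlock "consistent" and make prioritization unobservable.

`resolve_mapping_conflict` is the controller-facing selection rule when a
single import must be chosen: highest priority, then most-trusted owner
context (lowest preference rank, default = declaration order), then
lexicographically smallest rule id — a total order, so selection is
deterministic and permutation-invariant.

## Monitoring algorithm

Sensor agents alert iff a reading falls **strictly outside** the inclusive
normal range (boundary values such as 60 bpm or 99 °F are normal, because
the ranges are stated as "between X and Y").  Alerts become fired rule
instances at the controller; when two or more fired instances conflict
(complementary head literals) the conflicting-rule set (CRS) is built from
every instance that conflicts with at least one other, and only its
maximum under (priority, PC-before-Env, rule id) executes.  Patient-care
(PC) agents outrank environmental (Env) agents by default.  Routing is
fixed per group: PC → doctor, caretaker, next of kin; Env → fire
department, emergency response unit, police department.  Alert severity
maps the danger calculus onto {normal, high, severe}: one detecting group
→ high, both → severe.

The halt flag is set only by an external authority event injected through
the scenario (the decision to take over lies outside the system); while
halted, readings are not processed and no events are appended until an
explicit reboot event clears the flag and the CRS state.

## Synthetic sensor streams

One reading per sensor per tick; the tick duration is configuration
metadata only.  Baselines draw from a normal distribution truncated to the
normal range, centred on the documented typical value (82 bpm for heart
rate; range midpoints or clinical norms otherwise) with spread equal to
10 % of the range width — smooth, bounded, and guaranteeing that an
unscheduled stream can never alert.  Scheduled anomalies replace the
baseline verbatim (absolute value or offset from the mean).  Streams are
seeded per sensor kind from the run seed, so a fixed (scenario, seed) pair
reproduces byte-identical traces.

Default thresholds: heart rate 60–100 bpm; body temperature 97–99 °F; ECG
interval 0.6–1.2 s; EMG amplitude 50 µV–30 mV; EEG ≥ 8 Hz normal with
≤ 7 Hz abnormal in awake adults (the source prose attributes the 7 Hz
criterion to EMG, almost certainly meaning EEG; it is kept, labelled, on
both specs rather than silently corrected); CO normal 0.5–15 ppm (union of
the typical 0.5–5 ppm and properly-fixed-stove 5–15 ppm bands) with the
30 ppm figure kept as `alert_threshold_ppm` metadata.  Systolic/diastolic
blood pressure (90–120 / 60–80 mmHg), CO₂ (350–1000 ppm) and room
temperature (18–27 °C) have no documented thresholds in the case study;
their defaults follow common clinical/indoor norms and are marked
`non_paper` in the spec metadata and config comments.

The generator emulates threshold-crossing behaviour only.  It does not
model physiological waveform morphology, circadian or activity-driven
drift, sensor noise artefacts, dropout, or correlations between vitals —
so passing tests demonstrate the correctness of the reasoning and alerting
pipeline on clean, in-range-unless-scheduled signals, not robustness to
real-world signal quality.

## Temporal checks

Properties are evaluated with finite-trace semantics over tick-states (the
events sharing a tick): `G` is vacuously true and `F` false on the empty
trace, giving the duality `F p ≡ ¬G ¬p` and prefix-monotonicity of `F`.
Ask/tell pairing requires each `ask(j→i, φ)` to be followed (same tick or
later) by `tell(i→j, φ)` or covered by a declared standing tell rule.
The danger level is `H` iff exactly one of the two triggering formulas is
detected, `S` iff both, undefined iff neither.  Branching-time (CTL*-style)
checking is out of scope: the simulator produces exactly one path per
seed, so the recorded-path reading is the checkable one.

## Agent rosters

The source case study is internally inconsistent about its roster (a
nine-agent heading above a ten-agent list, and a seven-agent simulated
prototype).  Both readings ship as scenarios: `parkinsons_case_study.yaml`
with the full ten-sensor list (seven patient-care vitals, three
environmental signals) and `netlogo_replica.yaml` with the prototype's six
sensor agents plus the implicit controller.  Bundled context theories are
reconstructions from the published threshold prose — the original rule
figures are not reproduced in the source text — and are marked as such in
the scenario comments.

## Problem sizes and numerical choices

The oracle-equivalence suites use 500 random theories of at most 10 rules
over 6 atoms (engine and oracle each run in well under a minute at this
size); duality uses 1000 random traces of up to 15 events; the end-to-end
determinism check replays the 200-tick case study and runs 100 clean seeds
at 50 ticks each.  Per-tick equilibrium checks are memoized on the set of
abnormal-reading facts per context, so a quiet run computes the MCS
fixpoint once.  All randomness flows through seeded NumPy generators;
sorting (agent ids, mapping ids, context ids) fixes every remaining
iteration order, which is what makes traces byte-identical across runs.

## Known limitations

* The defeasible engine is propositional; no variables or rule schemata.
* Ambiguity-propagating and well-founded variants are not implemented.
* Distributed queries report support sets for positive answers only.
* The `undefined` taint is conservative: a cycle cut during evaluation of
  an unrelated mapping can mark a genuinely negative answer `undefined`.
* Message delivery to authorities is a logged event, not an integration
  with any real notification channel.
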