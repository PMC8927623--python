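# cdl-sentinel

Rule-based clinical decision support for continuous patient/home
monitoring, built on **contextual defeasible logic (CDL)**.  The package is
aimed at researchers and engineers prototyping ambient-assisted-living or
smart-hospital systems in which several independent knowledge sources
(*contexts*) — e.g. a smart home and a smart hospital — exchange
conclusions and can therefore feed each other contradictory information.

The package provides:

* **`rule_engine`** — a propositional defeasible-logic proof kernel.  A
  theory `D = (F, R, >)` has facts `F`, rules `R` partitioned into strict
  rules (`A → p`), defeasible rules (`A ⇒ p`) and defeaters (`A ⇝ p`, which
  only block), and an acyclic superiority relation `>` over conflicting
  rules.  Conclusions carry the standard proof tags `+Δ/−Δ` (definite
  provability/refutability from facts and strict rules) and `+∂/−∂`
  (defeasible provability/refutability).  The semantics is
  ambiguity-blocking with team defeat; integer rule priorities induce
  superiority between conflicting rules, and explicit pairs override them.
* **`context_network`** — a multi-context system: contexts with local
  theories linked by prioritized *mapping (bridge) rules* whose bodies
  reference foreign literals.  Distributed queries recurse across contexts
  (cycles terminate and taint the answer `undefined`), and
  `equilibrium_check` decides whether every context's belief set is
  consistent and every cross-context conflict actually resolved.
* **`agent_world`** — sensor agents with documented normal ranges, a
  controller running the monitoring algorithm (alert iff a reading leaves
  its range; on simultaneous conflicting rule firings build the
  conflicting-rule set CRS and execute only its highest-priority member,
  patient-care agents outranking environmental ones), authority routing
  (medical vs. civil), halt/reboot flag semantics, and a FIPA-style
  tell/ask/alert message codec.
* **`sensor_synth`** — deterministic synthetic sensor streams: truncated
  normal baselines that never leave the normal range, exact scheduled
  anomalies, and cross-context contradiction injection.
* **`trace_logic`** — finite-trace `G`/`F` property checking over recorded
  runs, ask/tell protocol pairing, and the danger-level calculus
  (`H` when one triggering formula is detected, `S` when both).
* **`scenario_cli`** — YAML scenario configs, end-to-end deterministic
  runs, JSONL/CSV export and the `cdl-sentinel` command line.

Two scenarios ship with the package: `parkinsons_case_study` (ten sensor
agents over a smart-home + smart-hospital MCS) and `netlogo_replica` (the
smaller seven-agent prototype roster).

## Worked example

Run a 200-tick scenario with a scheduled body-temperature spike of
103 °F at tick 40 (normal range 97–99 °F):

```bash
cdl-sentinel run scenario.yaml --out out/
```

```
anomaly_demo: 1 alert(s), exit state RUNNING, equilibrium violations 0
  route [doctor,caretaker,next_of_kin]: 1
  wrote out/trace.jsonl and alerts.csv
```

Exactly one alert fires, at the anomalous tick, and is routed to the
medical authorities (the agent is a patient-care agent); the system keeps
running and the multi-context system stays in equilibrium at every tick.
The trace records the FIPA-style alert message and the routed alert:

```
{"kind": "message", "payload": {"content": "Abnormal Body Temperature Detected",
 "performative": "alert", "receiver": "controller",
 "sender": "body_temperature_agent"}, "tick": 40}
{"kind": "alert", "payload": {"literal": "emergency",
 "route": ["doctor", "caretaker", "next_of_kin"], "severity": "high",
 "source": "body_temperature_agent"}, "tick": 40}
```

A distributed query against the bundled case study (no abnormal readings)
shows the hospital's decision context concluding the all-clear, supported
both locally and through the home context's mapping rule:

```bash
$ cdl-sentinel query parkinsons_case_study.yaml smart_hospital '~emergency'
smart_hospital |~ ~emergency: positive
  via smart_home:home_all_clear
  via smart_hospital:hosp_all_clear
  via smart_hospital:m_home_clear
```

Library use mirrors the CLI:

```python
from cdl_sentinel.scenario_cli import bundled_scenario_path, load_scenario, run_scenario

config = load_scenario(bundled_scenario_path("parkinsons_case_study"))
result = run_scenario(config)          # seed 7, 200 ticks
assert result.alerts == []             # in-range baselines never alert
assert all(result.equilibrium)         # MCS consistent at every tick
```

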