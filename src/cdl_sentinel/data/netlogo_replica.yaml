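# Replica of the seven-agent prototype roster: a controller agent plus six
# sensor agents (BP, body temperature, heart rate, electrical activity,
# carbon level, room temperature).  The controller is implicit in the
# simulation engine; the six sensor agents are declared here.
name: netlogo_replica
seed: 7
ticks: 100
heartbeat_interval: 10

contexts:
  - id: smart_hospital
    rank: 1
    theory:
      rules:
        - {id: hosp_bp, body: [abnormal_systolic_bp], head: emergency, priority: 3}
        - {id: hosp_body_temperature, body: [abnormal_body_temperature], head: emergency, priority: 3}
        - {id: hosp_heart_rate, body: [abnormal_heart_rate], head: emergency, priority: 3}
        - {id: hosp_electrical, body: [abnormal_ecg_interval], head: emergency, priority: 3}
        - {id: hosp_all_clear, body: [], head: "~emergency", priority: 1}
  - id: smart_home
    rank: 2
    theory:
      rules:
        - {id: home_carbon, body: [abnormal_co], head: emergency, priority: 2}
        - {id: home_room_temperature, body: [abnormal_room_temperature], head: emergency, priority: 2}
        - {id: home_all_clear, body: [], head: "~emergency", priority: 1}

mappings:
  - {id: m_home_alert, owner: smart_hospital, body: ["smart_home:emergency"], head: emergency, priority: 2}
  - {id: m_home_clear, owner: smart_hospital, body: ["smart_home:~emergency"], head: "~emergency", priority: 1}

agents:
  - {id: bp_agent, sensor: systolic_bp, group: PC_Agent, context: smart_hospital, alert_rule: {priority: 3}}
  - {id: body_temperature_agent, sensor: body_temperature, group: PC_Agent, context: smart_hospital, alert_rule: {priority: 3}}
  - {id: heart_rate_agent, sensor: heart_rate, group: PC_Agent, context: smart_hospital, alert_rule: {priority: 3}}
  - {id: electrical_activity_agent, sensor: ecg_interval, group: PC_Agent, context: smart_hospital, alert_rule: {priority: 3}}
  - {id: carbon_level_agent, sensor: co, group: Env_Agent, context: smart_home, alert_rule: {priority: 2}}
  - {id: room_temperature_agent, sensor: room_temperature, group: Env_Agent, context: smart_home, alert_rule: {priority: 2}}

schedule: []
authority_events: []
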