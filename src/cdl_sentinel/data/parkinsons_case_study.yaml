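# Parkinson's-disease monitoring case study: a smart home and a smart
# hospital context linked by prioritized mapping rules, with the full
# ten-sensor agent roster (seven patient-care vitals, three environmental
# signals).  Context theories are reconstructions from the published
# threshold prose; the source work shows only fragments of its rule sets.
#
# Ranges for systolic/diastolic BP, CO2 and room temperature are NON-PAPER
# defaults (clinical/indoor norms); all other thresholds are the published
# ones.
name: parkinsons_case_study
seed: 7
ticks: 200
heartbeat_interval: 25

contexts:
  - id: smart_hospital
    rank: 1
    theory:
      rules:
        - {id: hosp_heart_rate, body: [abnormal_heart_rate], head: emergency, priority: 3}
        - {id: hosp_body_temperature, body: [abnormal_body_temperature], head: emergency, priority: 3}
        - {id: hosp_systolic_bp, body: [abnormal_systolic_bp], head: emergency, priority: 3}
        - {id: hosp_diastolic_bp, body: [abnormal_diastolic_bp], head: emergency, priority: 3}
        - {id: hosp_ecg, body: [abnormal_ecg_interval], head: emergency, priority: 3}
        - {id: hosp_emg, body: [abnormal_emg_amplitude], head: emergency, priority: 3}
        - {id: hosp_eeg, body: [abnormal_eeg_frequency], head: emergency, priority: 3}
        - {id: hosp_all_clear, body: [], head: "~emergency", priority: 1}
  - id: smart_home
    rank: 2
    theory:
      rules:
        - {id: home_co, body: [abnormal_co], head: emergency, priority: 2}
        - {id: home_co2, body: [abnormal_co2], head: emergency, priority: 2}
        - {id: home_room_temperature, body: [abnormal_room_temperature], head: emergency, priority: 2}
        - {id: home_all_clear, body: [], head: "~emergency", priority: 1}

# The hospital's decision system imports the home's conclusion; a home
# emergency outranks the hospital's standing all-clear, while the home's
# all-clear is the weakest voice and yields to any abnormal vital sign.
mappings:
  - {id: m_home_alert, owner: smart_hospital, body: ["smart_home:emergency"], head: emergency, priority: 2}
  - {id: m_home_clear, owner: smart_hospital, body: ["smart_home:~emergency"], head: "~emergency", priority: 1}

agents:
  - {id: systolic_bp_agent, sensor: systolic_bp, group: PC_Agent, context: smart_hospital, alert_rule: {priority: 3}}
  - {id: diastolic_bp_agent, sensor: diastolic_bp, group: PC_Agent, context: smart_hospital, alert_rule: {priority: 3}}
  - {id: body_temperature_agent, sensor: body_temperature, group: PC_Agent, context: smart_hospital, alert_rule: {priority: 3}}
  - {id: heart_rate_agent, sensor: heart_rate, group: PC_Agent, context: smart_hospital, alert_rule: {priority: 3}}
  - {id: eeg_agent, sensor: eeg_frequency, group: PC_Agent, context: smart_hospital, alert_rule: {priority: 3}}
  - {id: ecg_agent, sensor: ecg_interval, group: PC_Agent, context: smart_hospital, alert_rule: {priority: 3}}
  - {id: emg_agent, sensor: emg_amplitude, group: PC_Agent, context: smart_hospital, alert_rule: {priority: 3}}
  - {id: co_agent, sensor: co, group: Env_Agent, context: smart_home, alert_rule: {priority: 2}}
  - {id: co2_agent, sensor: co2, group: Env_Agent, context: smart_home, alert_rule: {priority: 2}}
  - {id: room_temperature_agent, sensor: room_temperature, group: Env_Agent, context: smart_home, alert_rule: {priority: 2}}

schedule: []
authority_events: []
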