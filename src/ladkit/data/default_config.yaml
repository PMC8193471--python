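# Default LaD ruleset.
#
# Monitored parameters follow WHO intrapartum norms (FHR 110-160 bpm,
# systolic BP < 140 mm Hg, 3-5 contractions per 10 min, active-phase
# dilatation >= 1 cm/h assessed 4-hourly).  All values are overridable;
# the loader only enforces the structural contracts (scenario count,
# action count, rule coverage) declared under `meta`.

meta:
  name: lad-default
  active_phase_start_cm: 5
  expected_scenario_count: 1152
  expected_action_count: 22
  max_recommendation_actions: 16

parameters:
  - name: fetal_heart_rate
    value_kind: continuous
    unit: bpm
    physical_range: [0, 300]
    states: [abnormal_low, normal, abnormal_high]
    normal_states: [normal]
    bins:
      - {state: abnormal_low, below: 110}
      - {state: normal, upto: 160}
      - {state: abnormal_high}
    interval_minutes: 30
    applicable_stage: both

  - name: amniotic_fluid
    value_kind: categorical
    states: [membranes_intact, fluid_clear, opaque_or_foul]
    normal_states: [membranes_intact, fluid_clear]
    categories:
      intact: membranes_intact
      clear: fluid_clear
      opaque: opaque_or_foul
      foul: opaque_or_foul
      meconium: opaque_or_foul
    interval_minutes: 240
    applicable_stage: both

  # Raw value is the dilatation rate since the previous vaginal
  # examination, in cm/h; slower than 1 cm/h in the active phase is
  # slow progress.
  - name: cervical_dilatation
    value_kind: continuous
    unit: cm_per_hour
    physical_range: [0, 10]
    states: [slow_progress, adequate_progress]
    normal_states: [adequate_progress]
    bins:
      - {state: slow_progress, below: 1.0}
      - {state: adequate_progress}
    interval_minutes: 240
    applicable_stage: first_stage

  # Contractions counted over 10 minutes.
  - name: uterine_contractions
    value_kind: continuous
    unit: per_10_min
    physical_range: [0, 10]
    states: [inadequate, adequate, excessive]
    normal_states: [adequate]
    bins:
      - {state: inadequate, below: 3}
      - {state: adequate, upto: 5}
      - {state: excessive}
    interval_minutes: 30
    applicable_stage: both

  # Systolic pressure, mm Hg.
  - name: blood_pressure
    value_kind: continuous
    unit: mmHg
    physical_range: [0, 300]
    states: [hypotensive, normal, hypertensive]
    normal_states: [normal]
    bins:
      - {state: hypotensive, below: 90}
      - {state: normal, below: 140}
      - {state: hypertensive}
    interval_minutes: 240
    applicable_stage: both

  # Station of the presenting part relative to the ischial spines
  # (-5..+5); tracked in the second stage as a surrogate for descent.
  - name: fetal_station
    value_kind: continuous
    unit: station
    physical_range: [-5, 5]
    states: [high, descending]
    normal_states: [descending]
    bins:
      - {state: high, below: 0}
      - {state: descending}
    interval_minutes: 30
    applicable_stage: second_stage

# Scenario-space factorization: 3 x 4 x 4 x 4 x 2 x 3 = 1152.
# Management recursion is encoded statically: "recovered"/"responding"
# coordinates mean first-line management succeeded, "persistent"/
# "arrested" mean it failed.
factorization:
  - name: amniotic_status
    states: [membranes_intact, fluid_clear, fluid_opaque_or_foul]
    normal_states: [membranes_intact, fluid_clear]
  - name: fetal_heart_rate
    states: [normal, abnormal_recovered, abnormal_persistent, critical]
    normal_states: [normal]
  - name: cervical_progress
    states: [adequate, slow_responding, slow_persistent, arrested]
    normal_states: [adequate]
  - name: uterine_contractions
    states: [adequate, inadequate_responding, inadequate_persistent, hyperstimulation]
    normal_states: [adequate]
  - name: blood_pressure
    states: [normal, hypertensive]
    normal_states: [normal]
  - name: fetal_descent
    states: [advancing, delayed_recovered, arrested]
    normal_states: [advancing]

actions:
  - {action_id: 1,  label: "Continue routine monitoring per schedule",          category: observe}
  - {action_id: 2,  label: "Reassess the parameter after 30 minutes",           category: observe}
  - {action_id: 3,  label: "Repeat vaginal examination in 4 hours",             category: observe}
  - {action_id: 4,  label: "Turn mother to left lateral position",              category: intervene}
  - {action_id: 5,  label: "Start intravenous fluids",                          category: intervene}
  - {action_id: 6,  label: "Give oxygen by face mask",                          category: intervene}
  - {action_id: 7,  label: "Stop oxytocin infusion if running",                 category: intervene}
  - {action_id: 8,  label: "Augment labor with oxytocin",                       category: intervene}
  - {action_id: 9,  label: "Perform artificial rupture of membranes",           category: intervene}
  - {action_id: 10, label: "Give antihypertensive therapy",                     category: intervene}
  - {action_id: 11, label: "Start broad-spectrum antibiotics",                  category: intervene}
  - {action_id: 12, label: "Empty the bladder (catheterize if needed)",         category: intervene}
  - {action_id: 13, label: "Give tocolytic for uterine tachysystole",           category: intervene}
  - {action_id: 14, label: "Start continuous electronic fetal monitoring",      category: observe}
  - {action_id: 15, label: "Inform the senior obstetrician on duty",            category: escalate}
  - {action_id: 16, label: "Refer to a comprehensive obstetric care facility",  category: escalate}
  - {action_id: 17, label: "Prepare theatre for possible cesarean section",     category: escalate}
  - {action_id: 18, label: "Perform cesarean section",                          category: deliver}
  - {action_id: 19, label: "Perform assisted vaginal delivery (vacuum/forceps)", category: deliver}
  - {action_id: 20, label: "Encourage upright posture and mobilization",        category: intervene}
  - {action_id: 21, label: "Recheck blood pressure after 30 minutes of rest",   category: observe}
  - {action_id: 22, label: "Counsel the mother and document findings",          category: observe}

# Per-abnormality management rules.  `resolved` records whether the
# first-line response encoded in the coordinate succeeded; `critical`
# marks abnormalities whose persistence mandates expedited delivery.
rules:
  amniotic_status:
    fluid_opaque_or_foul: {actions: [11, 14, 15], resolved: false, critical: false}
  fetal_heart_rate:
    abnormal_recovered:   {actions: [4, 6, 14],    resolved: true,  critical: false}
    abnormal_persistent:  {actions: [4, 6, 7, 14], resolved: false, critical: true}
    critical:             {actions: [6, 7, 12, 14], resolved: false, critical: true}
  cervical_progress:
    slow_responding:      {actions: [8, 9],        resolved: true,  critical: false}
    slow_persistent:      {actions: [8, 9, 15],    resolved: false, critical: false}
    arrested:             {actions: [9, 15, 17],   resolved: false, critical: true}
  uterine_contractions:
    inadequate_responding: {actions: [8],          resolved: true,  critical: false}
    inadequate_persistent: {actions: [8, 9],       resolved: false, critical: false}
    hyperstimulation:      {actions: [7, 13, 14],  resolved: false, critical: false}
  blood_pressure:
    hypertensive:         {actions: [10, 21, 15],  resolved: false, critical: false}
  fetal_descent:
    delayed_recovered:    {actions: [4, 12],       resolved: true,  critical: false}
    arrested:             {actions: [12, 17, 19],  resolved: false, critical: true}

# Final decision by management outcome tier; tiers are cumulative so
# escalation actions are never lost when severity increases.
final_decision:
  routine:  [1]
  escalate: [15, 17]
  deliver:  [15, 17, 18]
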