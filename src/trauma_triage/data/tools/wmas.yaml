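# Grouped four-step triage tool, WMAS-style (intermediate accuracy).
# Placeholder variable lists; see las.yaml.
service_label: WMAS
grouped: true
steps:
  - index: 1
    label: physiology
    mandatory: true
    criteria:
      - {variable: GCS, comparator: "<=", threshold: 13, description: "GCS 13 or less"}
      - {variable: SBP, comparator: "<=", threshold: 90, sustained: true, description: "sustained systolic BP 90 mmHg or below"}
      - {variable: RR, comparator: "<", threshold: 10, description: "respiratory rate below 10"}
      - {variable: RR, comparator: ">=", threshold: 30, description: "respiratory rate 30 or above"}
  - index: 2
    label: anatomy
    mandatory: true
    criteria:
      - variable: injury_pattern
        comparator: in
        threshold: [penetrating_torso, penetrating_head_neck, open_fracture, major_chest_injury]
        description: "penetrating torso/head-neck, open fracture or major chest injury"
  - index: 3
    label: mechanism
    mandatory: false
    criteria:
      - variable: mechanism
        comparator: in
        threshold: [fall_gt_1m, rta_pedestrian, rta_motor_vehicle, gunshot]
        description: "high-energy mechanism"
  - index: 4
    label: special_circumstances
    mandatory: false
    criteria:
      - {variable: age, comparator: ">=", threshold: 65, description: "older patient"}
      - variable: special_circumstance
        comparator: in
        threshold: [anticoagulant_use]
        description: "anticoagulated patient"
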