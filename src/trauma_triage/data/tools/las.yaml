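# Grouped four-step major-trauma triage tool, LAS-style (most sensitive of
# the four fixtures).  Placeholder variable lists built from conventional
# field-triage criteria: real deployments must substitute the service's
# authentic checklist.
service_label: LAS
grouped: true
steps:
  - index: 1
    label: physiology
    mandatory: true
    criteria:
      - {variable: GCS, comparator: "<=", threshold: 13, description: "GCS 13 or less"}
      - {variable: SBP, comparator: "<", threshold: 90, description: "systolic BP below 90 mmHg"}
      - {variable: RR, comparator: "<", threshold: 10, description: "respiratory rate below 10"}
      - {variable: RR, comparator: ">", threshold: 29, description: "respiratory rate above 29"}
      - {variable: SpO2, comparator: "<", threshold: 90, description: "oxygen saturation below 90%"}
  - index: 2
    label: anatomy
    mandatory: true
    criteria:
      - variable: injury_pattern
        comparator: in
        threshold: [penetrating, open_fracture, two_or_more_body_regions, major_chest_injury]
        description: "penetrating injury, open fracture, multi-region or major chest injury"
  - index: 3
    label: mechanism
    mandatory: false
    criteria:
      - variable: mechanism
        comparator: in
        threshold: [fall_gt_1m, rta_pedestrian, rta_motorcycle, rta_bicycle, gunshot]
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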