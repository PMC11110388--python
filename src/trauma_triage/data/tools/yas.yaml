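# Grouped four-step triage tool, YAS-style (intermediate accuracy).
# Placeholder variable lists; see las.yaml.
service_label: YAS
grouped: true
steps:
  - index: 1
    label: physiology
    mandatory: true
    criteria:
      - {variable: GCS, comparator: "<", threshold: 14, description: "GCS below 14"}
      - {variable: SBP, comparator: "<", threshold: 90, description: "systolic BP below 90 mmHg"}
      - {variable: RR, comparator: ">", threshold: 29, description: "respiratory rate above 29"}
      - {variable: SpO2, comparator: "<", threshold: 92, description: "oxygen saturation below 92%"}
  - index: 2
    label: anatomy
    mandatory: true
    criteria:
      - variable: injury_pattern
        comparator: in
        threshold: [penetrating, open_fracture, two_or_more_body_regions]
        description: "penetrating injury, open fracture or multi-region injury"
  - index: 3
    label: mechanism
    mandatory: false
    criteria:
      - variable: mechanism
        comparator: in
        threshold: [fall_gt_1m, rta_motorcycle, rta_pedestrian]
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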