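# Ungrouped single-checklist triage tool, SWAS-style (most specific of the
# four fixtures: strict thresholds, sustained hypotension, narrow anatomy
# list).  Placeholder variable lists; see las.yaml.
service_label: SWAS
grouped: false
steps:
  - index: 1
    label: ungrouped
    mandatory: true
    criteria:
      - {variable: GCS, comparator: "<=", threshold: 13, description: "GCS 13 or less"}
      - {variable: SBP, comparator: "<", threshold: 90, sustained: true, description: "sustained systolic BP below 90 mmHg"}
      - {variable: RR, comparator: "<", threshold: 10, description: "respiratory rate below 10"}
      - {variable: RR, comparator: ">", threshold: 29, description: "respiratory rate above 29"}
      - variable: injury_pattern
        comparator: in
        threshold: [penetrating_torso, open_fracture, major_chest_injury]
        description: "penetrating torso, open fracture or major chest injury"
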