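# Variant of mitigation package A with the length-of-stay cut applied to
# IAPT therapy only (the narrower reading of the intervention's scope).
name: intervention_a_table1
reference_date: 2021-04-01
demand_segments:
  - services:
      - L2_GP_high
      - L2_GP_low
      - L3_IAPT_social_prescribing
      - L3_IAPT_therapy
      - L4_MHP_crisis
      - L5_AWP_inpatient
    start: 2021-04-01
    end: 2021-10-01
    multiplier: 2.0
  - services: [L3_IAPT_assessment]
    start: 2021-04-01
    end: 2022-04-01
    multiplier: 0.8
  - services: [L3_IAPT_assessment]
    start: 2022-04-01
    end: 2022-10-01
    multiplier: 1.25
intervention:
  capacity:
    - services: [L2_GP_high, L2_GP_low]
      factor: 1.3
      start: 2021-04-01
      end: 2022-10-01
  los:
    - services: [L3_IAPT_therapy]
      factor: 0.8
      start: 2022-04-01
      end: 2022-10-01
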