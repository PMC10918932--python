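# Mitigation package B on top of demand trajectory B, extending package A:
# package A's GP capacity and LOS measures, plus 20%/30% more capacity at
# MHP general/specialist, community specialist stays cut from 78 to 70
# weeks (about 10%), and 30% more flow from MHP specialist to MHP general
# and crisis.  The additional measures run April 2021 - October 2022.
name: intervention_b
reference_date: 2021-04-01
demand_segments:
  - services: &primary
      - L2_GP_high
      - L2_GP_low
      - L3_IAPT_assessment
      - L3_IAPT_social_prescribing
      - L3_IAPT_therapy
    start: 2020-04-01
    end: 2021-04-01
    multiplier: 1.22
  - services: *primary
    start: 2021-04-01
    end: 2022-04-01
    multiplier: 1.20
  - services: *primary
    start: 2022-04-01
    end: 2023-04-01
    multiplier: 1.12
  - services: &secondary
      - L4_MHP_general
      - L4_MHP_specialist
      - L4_MHP_triage
    start: 2020-04-01
    end: 2021-04-01
    multiplier: 1.25
  - services: *secondary
    start: 2021-04-01
    end: 2022-04-01
    multiplier: 1.24
  - services: *secondary
    start: 2022-04-01
    end: 2023-04-01
    multiplier: 1.14
  - services: [L4_MHP_crisis]
    start: 2020-04-01
    end: 2021-04-01
    multiplier: 1.13
  - services: [L4_MHP_crisis]
    start: 2021-04-01
    end: 2022-04-01
    multiplier: 1.12
  - services: [L4_MHP_crisis]
    start: 2022-04-01
    end: 2023-04-01
    multiplier: 1.07
  - services: [L5_AWP_inpatient]
    start: 2021-04-01
    end: 2022-04-01
    multiplier: 1.01
intervention:
  capacity:
    - services: [L2_GP_high, L2_GP_low]
      factor: 1.3
      start: 2021-04-01
      end: 2022-10-01
    - services: [L4_MHP_general]
      factor: 1.2
      start: 2021-04-01
      end: 2022-10-01
    - services: [L4_MHP_specialist]
      factor: 1.3
      start: 2021-04-01
      end: 2022-10-01
  los:
    - services:
        - L3_IAPT_therapy
        - L4_MHP_general
        - L4_MHP_crisis
        - L4_MHP_triage
      factor: 0.8
      start: 2022-04-01
      end: 2022-10-01
    - services: [L4_MHP_specialist]
      target_mean_weeks: 70
      start: 2021-04-01
      end: 2022-10-01
  flow:
    - source: L4_MHP_specialist
      target: L4_MHP_general
      factor: 1.3
      start: 2021-04-01
      end: 2022-10-01
    - source: L4_MHP_specialist
      target: L4_MHP_crisis
      factor: 1.3
      start: 2021-04-01
      end: 2022-10-01
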