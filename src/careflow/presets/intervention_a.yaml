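# Mitigation package A on top of demand trajectory A: 30% more level-2
# (GP) capacity from April 2021 to October 2022, and a 20% shorter stay in
# IAPT therapy and the level-4 community services from April to October
# 2022.  (A narrower variant restricting the LOS cut to IAPT therapy only
# ships as intervention_a_table1.)
name: intervention_a
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
    - services:
        - L3_IAPT_therapy
        - L4_MHP_general
        - L4_MHP_specialist
        - L4_MHP_crisis
        - L4_MHP_triage
      factor: 0.8
      start: 2022-04-01
      end: 2022-10-01
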