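# Post-pandemic demand trajectory B: fiscal-year (April-March) uplifts.
# Primary mental health (GP + IAPT) +22% / +20% / +12% over 2020/21,
# 2021/22 and 2022/23; secondary community care +25% / +24% / +14%;
# crisis +13% / +12% / +7%; specialist inpatient +1% in 2021/22 and
# nothing by 2022/23.
name: baseline_b
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
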