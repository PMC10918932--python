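# Post-pandemic demand trajectory A: a doubling of demand from April 2021
# for GP, crisis and inpatient care (levels 2, 3 and 5), reverting to
# pre-pandemic levels in October 2021.  IAPT assessment instead sees a 20%
# drop from April 2021 and a 25% rise from April 2022, reverting in
# October 2022.  Whether level-4 crisis belongs to the doubling set is
# ambiguous in the source description; this preset includes it (and keeps
# IAPT assessment on its own trajectory) -- edit the service lists to
# change that reading.
name: baseline_a
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
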