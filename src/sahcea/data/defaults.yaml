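# sahcea base-case parameters (published point estimates)
start_age: 55
prevalence_aneurysm: 0.173
outcome_rebleed:
- 0.0752
- 0.3948
- 0.53
outcome_elective:
- 0.51
- 0.34
- 0.15
outcome_no_aneurysm_favorable: 0.8708
outcome_no_aneurysm_unfavorable: 0.0792
state_mortality:
- 0.1067
- 0.7778
- 0.1155
cta_sensitivity: 0.98
cta_specificity: 1.0
dsa_specificity: 1.0
cost_cta: 331.0
cost_dsa: 1919.0
cost_hospital_day: 380.75
los_days: 7
cost_elective_coiling: 14030.8
cost_elective_clipping: 13212.19
cost_emergency_coiling: 19983.87
cost_emergency_clipping: 20275.02
coiling_fraction: 0.5
cost_nursing_unfavorable_annual: 84346.39
utility_favorable: 0.87
utility_unfavorable: 0.44
utility_dead: 0.0
utility_no_rebleed: 0.6
discount_qaly: 0.035
discount_cost: 0.035
stop_age: 100
half_cycle_correction: false
rebleed_reward_same_cycle: false
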