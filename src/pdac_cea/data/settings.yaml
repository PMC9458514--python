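# Run-level settings and modelling options.
horizon_cycles: 144          # 12 years of monthly cycles
cycle_length_months: 1.0
discount_rate_annual: 0.03
wtp_thresholds: [50000, 100000, 150000]
psa_iterations: 10000
rng_seed: 1
# Allocation of neoadjuvant non-completers (second-line / palliative / death).
dropout_split_second_line: 0.5
dropout_split_palliative: 0.3
dropout_split_death: 0.2
# Assumed median palliative survival (months) for the treated arms; the
# untreated arm's post-progression survival is calibrated instead.
palliative_median_months: 5.1
surgery_recovery_cycles: 1
chemoradiation_addon: true
recurrence_second_line: true
toxicity_hospitalization_inpatient: true
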