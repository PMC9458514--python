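# Gemcitabine + nab-paclitaxel arm: 6 neoadjuvant cycles (28-day schedule,
# day 1, 8 and 15 infusions).
name: G-nP
treated: true
n_cycles: 6
cycle_days: "28-day schedule, day 1, 8 and 15 infusions"
dropout_rate: {base: 0.31, low: 0.14, high: 0.39}
toxicity_rate: {base: 0.65, low: 0.15, high: 0.75}
hospitalization_for_toxicity: {base: 0.25, low: 0.15, high: 0.35}
surgical_complication_rate: {base: 0.23, low: 0.15, high: 0.40}
fistula_rate: {base: 0.0, low: 0.0, high: 0.015}
r0_rate: {base: 0.81, low: 0.44, high: 0.88}
recurrence_rate: {base: 0.53, low: 0.29, high: 0.65}
lymph_node_positivity: {base: 0.72, low: 0.71, high: 0.86}
median_surv_recurrence_r0: {base: 18.7, low: 16, high: 21}
median_surv_recurrence_r1: {base: 16, low: 14, high: 18}
median_surv_recurrence_n0: {base: 20, low: 18, high: 22}
median_surv_recurrence_n1: {base: 16, low: 14, high: 18}
median_surv_second_line: {base: 9, low: 7, high: 11}
cost_chemo_cycle: {base: 8882.41, low: 8000.00, high: 10000.00}
cost_toxicity_cycle: {base: 918.00, low: 734.40, high: 1101.60}
cost_second_line_month: {base: 4080.00, low: 3000.00, high: 4800.00}
cost_toxicity_second_line_month: {base: 2094.75, low: 1675.80, high: 2513.70}
cost_admin_month: {base: 568.98, low: 450.00, high: 700.00}
disutility_chemo: {base: -0.041, low: -0.071, high: -0.031}
disutility_toxicity: {base: -0.10, low: -0.11, high: -0.091}
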