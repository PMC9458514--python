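# FOLFIRINOX arm: 6 neoadjuvant cycles (28-day schedule, day 1 and 15 infusions).
name: FOLFIRINOX
treated: true
n_cycles: 6
cycle_days: "28-day schedule, day 1 and 15 infusions"
dropout_rate: {base: 0.35, low: 0.33, high: 0.40}
toxicity_rate: {base: 0.75, low: 0.287, high: 0.85}
hospitalization_for_toxicity: {base: 0.37, low: 0.26, high: 0.46}
surgical_complication_rate: {base: 0.36, low: 0.29, high: 0.43}
fistula_rate: {base: 0.05, low: 0.0, high: 0.05}
r0_rate: {base: 0.85, low: 0.40, high: 0.88}
recurrence_rate: {base: 0.61, low: 0.29, high: 0.65}
lymph_node_positivity: {base: 0.56, low: 0.50, high: 0.62}
median_surv_recurrence_r0: {base: 21, low: 19, high: 23}
median_surv_recurrence_r1: {base: 17, low: 15, high: 19}
median_surv_recurrence_n0: {base: 22, low: 20, high: 24}
median_surv_recurrence_n1: {base: 18, low: 16, high: 20}
median_surv_second_line: {base: 9, low: 7, high: 11}
cost_chemo_cycle: {base: 863.50, low: 760.00, high: 960.00}
cost_toxicity_cycle: {base: 1734.00, low: 1387.20, high: 2080.80}
cost_second_line_month: {base: 13209.00, low: 0.00, high: 14800.00}
cost_toxicity_second_line_month: {base: 6778.80, low: 5423.04, high: 9490.32}
cost_admin_month: {base: 578.79, low: 450.00, high: 700.00}
disutility_chemo: {base: -0.12, low: -0.19, high: -0.05}
disutility_toxicity: {base: -0.24, low: -0.28, high: -0.19}
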