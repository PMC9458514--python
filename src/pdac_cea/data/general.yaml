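# General model parameters (base value with deterministic sensitivity range).
# All costs in 2021 USD; utilities are health-state weights in [0, 1].
start_age: {base: 60, low: 38, high: 66}
neoadjuvant_30day_mortality: {base: 0.24, low: 0.17, high: 0.57}
surgical_30day_mortality: {base: 0.015, low: 0.01, high: 0.053}
postsurgical_fistula_rate: {base: 0.093, low: 0.0, high: 0.24}
utility_progression_free: {base: 0.80, low: 0.68, high: 0.88}
utility_progressive: {base: 0.73, low: 0.62, high: 0.80}
utility_palliative: {base: 0.14, low: 0.0, high: 0.34}
utility_surgery_recovery: {base: 0.78, low: 0.78, high: 0.81}
cost_resection: {base: 29580.00, low: 15000.00, high: 41000.00}
cost_palliative_total: {base: 101388.00, low: 92820.00, high: 103020.00}
cost_capecitabine_rt_month: {base: 1377.00, low: 840.00, high: 1938.00}
cost_chemoradiation_hosp: {base: 2856.00, low: 1734.00, high: 3774.00}
cost_eus: {base: 1570.80, low: 0.00, high: 1570.80}
cost_pdac_month_inpatient: {base: 5508.00, low: 3162.00, high: 7446.00}
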