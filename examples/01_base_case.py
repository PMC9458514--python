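"""Base case: calibrate all three strategies, run the cohorts, rank them.

Prints the base-case summary (one row per strategy) and the efficiency
frontier.  Costs are discounted 2021 USD, QALYs/life-years discounted at 3%
per year; the ICER column is each strategy's cost per extra QALY against the
next-cheaper non-dominated strategy.
"""

from pdac_cea.pipeline import load_inputs, run_base_case, summary_table

run = run_base_case(load_inputs(), seed=1)
print(summary_table(run).round(2).to_string(index=False))
print()
for wtp, best in run.frontier.optimal.items():
    print(f"optimal at WTP ${wtp:,.0f}/QALY: {best}")
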