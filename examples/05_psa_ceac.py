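"""Probabilistic sensitivity analysis and acceptability curves.

All ranged inputs are sampled jointly (beta for probabilities/utilities,
gamma for costs and medians, mean-anchored at base) and the model re-run per
draw; the CEAC reports how often each strategy maximises net monetary
benefit as willingness-to-pay varies.  2,000 draws here for speed; the full
analysis uses settings.psa_iterations (10,000).
"""

from pdac_cea.pipeline import load_inputs, run_base_case
from pdac_cea.sensitivity import run_psa

run = run_base_case(load_inputs(), seed=1)
res = run_psa(run, iterations=2000, seed=1)
for wtp, shares in res.optimal_share.items():
    line = ", ".join(f"{name}: {100 * s:.1f}%" for name, s in shares.items())
    print(f"WTP ${wtp:,.0f}/QALY -> {line}")
print("\n(share = fraction of simulations in which the strategy is optimal)")
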