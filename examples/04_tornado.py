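"""One-way deterministic sensitivity analysis (tornado).

Each input is swept across its published range with everything else at base;
the table reports the FOLFIRINOX-vs-G-nP ICER at both bounds.  Entries whose
adverse bound pushes the ICER past $100,000/QALY (or into dominance) would
change the treatment recommendation.
"""

from pdac_cea.pipeline import load_inputs, run_base_case
from pdac_cea.sensitivity import one_way_dsa, tornado_frame

run = run_base_case(load_inputs(), seed=1)
entries = one_way_dsa(run, wtp=100_000.0)
df = tornado_frame(entries)
print(df.head(12).to_string(index=False))
print("\nparameters whose excursion changes the decision at $100k/QALY:")
for e in entries:
    if e.crosses_wtp:
        print(" -", e.parameter)
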