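# Abridged all-cause mortality: average of male and female annual death
# probabilities (qx), U.S. Social Security Administration period life table,
# 2016, ages 60-72 (the 12-year model horizon starting at age 60).
age,annual_mortality
60,0.0088
61,0.0095
62,0.0102
63,0.0109
64,0.0117
65,0.0126
66,0.0136
67,0.0146
68,0.0157
69,0.0170
70,0.0185
71,0.0201
72,0.0219
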