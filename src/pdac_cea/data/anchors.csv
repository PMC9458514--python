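arm,endpoint,time_months,survival
FOLFIRINOX,OS,0,1.0
FOLFIRINOX,OS,34.01,0.5
FOLFIRINOX,OS,60,0.2938
FOLFIRINOX,OS,120,0.0973
FOLFIRINOX,PFS,0,1.0
FOLFIRINOX,PFS,29.54,0.5
FOLFIRINOX,PFS,60,0.2568
FOLFIRINOX,PFS,120,0.0848
G-nP,OS,0,1.0
G-nP,OS,28.27,0.5
G-nP,OS,60,0.2133
G-nP,OS,120,0.0524
G-nP,PFS,0,1.0
G-nP,PFS,24.88,0.5
G-nP,PFS,60,0.1792
G-nP,PFS,120,0.0438
Natural history,OS,0,1.0
Natural history,OS,13,0.5
Natural history,OS,60,0.002
Natural history,OS,120,0.0001
Natural history,PFS,0,1.0
Natural history,PFS,7.87,0.5
Natural history,PFS,60,0.0001
Natural history,PFS,120,0.0001
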