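# Untreated comparator: no neoadjuvant therapy, no surgery.
name: Natural history
treated: false
n_cycles: 0
cycle_days: ""
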