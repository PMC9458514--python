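# Center-of-excellence scenario — SYNTHETIC override values.
# The published scenario adjusted dropout, recurrence and R0 rates and the
# survival targets to center-of-excellence literature, but the exact values
# live in an unavailable supplement.  These placeholders follow the published
# qualitative direction only: fewer patients reach resection (higher
# dropout), lower recurrence, higher R0, longer survival.  Scenario outputs
# are illustrative, not reproductions.
name: center-of-excellence (synthetic)
strategies:
  FOLFIRINOX:
    dropout_rate: 0.415
    recurrence_rate: 0.55
    r0_rate: 0.88
  G-nP:
    dropout_rate: 0.47
    recurrence_rate: 0.48
    r0_rate: 0.85
anchors:
  - arm: FOLFIRINOX
    endpoint: OS
    points: [[0, 1.0], [39.0, 0.5], [60, 0.33], [120, 0.12]]
  - arm: FOLFIRINOX
    endpoint: PFS
    points: [[0, 1.0], [32.0, 0.5], [60, 0.29], [120, 0.10]]
  - arm: G-nP
    endpoint: OS
    points: [[0, 1.0], [37.5, 0.5], [60, 0.25], [120, 0.07]]
  - arm: G-nP
    endpoint: PFS
    points: [[0, 1.0], [28.0, 0.5], [60, 0.21], [120, 0.055]]
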