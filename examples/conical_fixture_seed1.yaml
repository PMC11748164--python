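dimension: 3
label: conical-fixture(seed=1, N=3)
v11:
  constant: 0.4145446433957134
  linear:
  - 2.0118216247002567
  - 0.0
  - 0.5390949260041344
  quadratic:
  - - 0.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 0.7162394190794505
v22:
  constant: 0.4145446433957134
  linear:
  - -2.0118216247002567
  - 0.0
  - 0.5390949260041344
  quadratic:
  - - 0.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 0.0
  - - 0.0
    - 0.0
    - 0.7162394190794505
v12:
  linear:
  - 0.0
  - 2.450463696325935
  - 0.0
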