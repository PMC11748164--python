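dimension: 2
label: isotropic-cone
v11:
  linear:
  - 1.0
  - 0.0
v22:
  linear:
  - -1.0
  - -0.0
v12:
  linear:
  - 0.0
  - 1.0
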