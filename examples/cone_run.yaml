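# Tube search on the textbook isotropic cone (E_pm = +-r, gap = 2r).
model: cone.yaml
epsilon: 0.2
x0: [1.5, 0.8]
out_prefix: cone_meci
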