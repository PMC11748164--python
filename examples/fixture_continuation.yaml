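# Stepwise continuation on a 3D conical fixture with a known MECI.
model: conical_fixture_seed1.yaml
schedule: [0.2, 0.02, 0.002]
x0: [1.0, 1.0, 0.0]
out_prefix: fixture_meci
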