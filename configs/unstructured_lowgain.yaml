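# Subcritical gain: the network contracts to a fixed point.
model: {N: 1000, D: 5, g: 0.5, T: 200, seed: 1}
weights: {preset: unstructured}
record: rates
output_dir: out/unstructured_lowgain
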