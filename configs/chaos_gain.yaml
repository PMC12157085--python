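# For `wtanet chaos`: perturbation-growth test at hard WTA.
model: {N: 1000, D: 5, g: inf, T: 30, seed: 6}
weights: {preset: unstructured}
record: rates
output_dir: out/chaos_gain
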