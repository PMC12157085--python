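# For `wtanet stability`: sweep D at the uniform state for the
# diagonal-dominant variance family; destabilizes at D = 11.
model: {N: 10, D: 16, g: inf, T: 10, seed: 0}
weights: {preset: multistable, mode: variance, diag: 13.0}
record: rates
output_dir: out/stability_sweep
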