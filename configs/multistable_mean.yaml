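# Mean-driven multistability ((mu_J)0 = 3): one population saturates,
# spiking becomes regular.
model: {N: 3000, D: 16, g: inf, T: 1500, seed: 3}
weights: {preset: multistable, mode: mean, diag: 3.0}
record: raster
output_dir: out/multistable_mean
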