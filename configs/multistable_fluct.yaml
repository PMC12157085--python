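# Fluctuation-driven multistability: zero mean weights, strong diagonal
# weight variances ((sigma_J)0 = 13). Several populations stay active.
model: {N: 3000, D: 16, g: inf, T: 1500, seed: 3}
weights: {preset: multistable, mode: variance, diag: 13.0, offdiag: 1.0}
record: raster
output_dir: out/multistable_fluct
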