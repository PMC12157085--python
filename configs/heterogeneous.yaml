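# Slow heterogeneous firing-rate dynamics from sparse off-diagonal
# variance couplings (K_sigma nonzero entries of (sigma_J^2)_r per row).
model: {N: 2000, D: 200, g: inf, T: 2000, seed: 5}
weights: {preset: heterogeneous, K_sigma: 10, var_r: 0.09, seed: 5}
record: raster
output_dir: out/heterogeneous
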