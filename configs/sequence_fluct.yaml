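# Fluctuation-driven sequence generation on a ring ((sigma_J)2 = 4.2).
model: {N: 2500, D: 16, g: inf, T: 2000, seed: 4}
weights: {preset: sequence, mode: variance, diag: 10.0, offdiag: 1.0, shift: 4.2}
record: raster
output_dir: out/sequence_fluct
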