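# Baseline unstructured network in the hard-WTA (spiking) regime:
# irregular Poisson-like spiking, population rates pinned at 1/D.
model: {N: 1000, D: 5, g: inf, T: 3000, seed: 1}
weights: {preset: unstructured}
record: raster
output_dir: out/unstructured_spiking
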