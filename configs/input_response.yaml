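# Transient input to populations 1-2 at t = 25; the unstructured network
# snaps back to the uniform state one step after the input ends.
model: {N: 2000, D: 5, g: inf, T: 60, seed: 2}
weights: {preset: unstructured}
input:
  - {t_start: 25, t_end: 26, u: [2.0, 2.0, 0.0, 0.0, 0.0], v: [0.0, 0.0, 0.0, 0.0, 0.0]}
record: rates
output_dir: out/input_response
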