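synthetic_preset: two_bloom
outdir: bloomdyn_out
network: {hidden_layers: 2, hidden_width: 16}
training: {iterations: 300, members: 5}
sindy: {kappa: 0.015}
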