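# No group difference: planted effect zero (chance-level benchmark)
n_p = 12
n_t = 120
n_per_group = 10
base_density = 0.10
n_diff_edges = 0
effect = 0.0
seed = 0
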