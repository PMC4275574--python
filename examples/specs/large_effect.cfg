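# Strong group difference: event-related study geometry at reduced regions
n_p = 20
n_t = 180
n_per_group = 19
base_density = 0.10
n_diff_edges = 5
effect = 0.5
seed = 0
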