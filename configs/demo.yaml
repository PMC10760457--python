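# Demonstration run: ~1-Mb synthetic genome with planted structure.
# Feature counts and lengths are desk-scale; intergenic gaps put the
# genome near 1 Mb while keeping the folded feature space modest.
seed: 1
synthetic:
  intergenic_gap: [8000, 13000]
  categories:
    gene:    {n: 20, structured_fraction: 0.5, position_bias: uniform,     true_skew: 0.8}
    RLC:     {n: 15, position_bias: five_prime,  true_skew: 0.5}
    RLG:     {n: 15, position_bias: five_prime,  true_skew: 0.5}
    DTM:     {n: 15, position_bias: either_end,  true_skew: 0.5, autonomous_fraction: 0.4}
    DHH:     {n: 15, position_bias: three_prime, true_skew: 0.6, autonomous_fraction: 0.4}
    control: {n: 10, structured_fraction: 0.0,   true_skew: 0.0}
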