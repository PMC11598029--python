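scenario: default
iterations: 1000
master_seed: 0
replicate_count: 5
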