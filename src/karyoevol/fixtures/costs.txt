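fusion: 1
fission: 5
inversion: 1
repositioning: 1
fusion_target: m
state_radius: 6
max_n: 30
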