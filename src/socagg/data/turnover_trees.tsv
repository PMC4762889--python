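component	spruce	pine	deciduous
foliage	0.143	0.33	1
branches	0.0125	0.027	0.025
coarse_roots	0.0125	0.027	0.025
fine_roots	0.6	0.6	0.6
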