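# Recommended harvest age (years) by dominant species and site productivity
# class (1 = low, 2 = medium, 3 = high). Configuration lookup used when
# reconstructing the previous rotation of young productive stands.
species	site_1	site_2	site_3
spruce	120	100	80
pine	130	110	90
deciduous	80	70	60
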