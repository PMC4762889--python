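layer	moss	lichen	herbs_grasses	dwarf_shrubs
above	0.33	0.1	1	0.25
below	nan	nan	0.33	0.33
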