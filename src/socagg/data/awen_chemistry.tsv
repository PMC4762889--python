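# Default chemical partition (A, W, E, N mass fractions of litter carbon) per
# species x component and per ground-vegetation class. These are editable
# configuration defaults in the range reported by litter-chemistry
# compilations, not measured values for any particular stand.
species	component	a	w	e	n
spruce	foliage	0.51	0.13	0.08	0.28
pine	foliage	0.52	0.13	0.09	0.26
deciduous	foliage	0.50	0.22	0.05	0.23
spruce	fine_roots	0.52	0.15	0.05	0.28
pine	fine_roots	0.52	0.15	0.05	0.28
deciduous	fine_roots	0.52	0.15	0.05	0.28
spruce	branches	0.66	0.02	0.02	0.30
pine	branches	0.66	0.02	0.02	0.30
deciduous	branches	0.65	0.03	0.02	0.30
spruce	coarse_roots	0.66	0.02	0.02	0.30
pine	coarse_roots	0.66	0.02	0.02	0.30
deciduous	coarse_roots	0.65	0.03	0.02	0.30
spruce	stem	0.66	0.01	0.01	0.32
pine	stem	0.68	0.01	0.01	0.30
deciduous	stem	0.65	0.02	0.01	0.32
spruce	stump	0.66	0.01	0.01	0.32
pine	stump	0.68	0.01	0.01	0.30
deciduous	stump	0.65	0.02	0.01	0.32
groundveg	moss	0.42	0.18	0.04	0.36
groundveg	lichen	0.44	0.18	0.06	0.32
groundveg	herbs_grasses	0.45	0.25	0.05	0.25
groundveg	dwarf_shrubs	0.47	0.15	0.08	0.30
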