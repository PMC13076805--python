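name	delta_mass	site_rule	per_site
disulfide_bond	-2.015650	C	1
reduction	2.015650	C	1
carbamidomethyl	57.021464	C	1
ring_open_hydration	18.010565	cyclic	0
amidation	-0.984016	cterm	0
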