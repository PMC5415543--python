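species	province	substrate	MHT	MHT_sem	LL50	UL50
Aratus_pisonii	Brazilian	Mangrove trees	27.0	0.6	12.8	36.9
Cardisoma_guanhumi	Brazilian	Sandy clay, supralittoral	26.2	0.4	13.4	38.6
Goniopsis_cruentata	Brazilian	Mangrove mud, under roots	28.2	0.8	12.8	36.0
Ocypode_quadrata	Brazilian	Sandy beaches, supralittoral	21.8	0.8	13.8	36.2
Pachygrapsus_transversus	Brazilian	Rocky shores	29.1	1.1	13.8	36.2
Uca_maracoani	Brazilian	Mangrove mud, deep burrows	36.3	0.5	12.8	38.6
Ucides_cordatus	Brazilian	Mangrove mud, under roots	22.1	1.5	15.5	39.0
Armases_rubripes	Argentinian	Under rocks, among Spartina	27.0	1.2	8.7	36.1
Neohelice_granulata	Argentinian	Sandy clay, among Spartina	25.5	0.7	6.5	36.7
Uca_uruguayensis	Argentinian	Sandy beaches, mesolittoral	29.3	1.4	10.4	39.3
Acanthocyclus_albatrossis	Magellanic	Under rocks, mesolittoral	1.5	0.1	-0.2	29.0
Halicarcinus_planatus	Magellanic	Under rocks, mesolittoral	1.4	0.1	-0.1	23.0
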