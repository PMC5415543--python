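species	locality	catalogue_number	genbank_accession
Acanthocyclus_albatrossis	Ushuaia, Argentina	CCDB 5738	KT279704
Aratus_pisonii	Ilha de Itamaraca, Brazil	CCDB 5732	KT279694
Armases_rubripes	Rio Grande, Brazil	CCDB 5735	KT279701
Cardisoma_guanhumi	Ipojuca, Brazil	CCDB 3927	KT279695
Goniopsis_cruentata	Tamandare, Brazil	MZUSP 29928	KT279696
Halicarcinus_planatus	Ushuaia, Argentina	CCDB 5739	KT279705
Neohelice_granulata	Rio Grande, Brazil	CCDB 5736	KT279702
Ocypode_quadrata	Ilha de Itamaraca, Brazil	CCDB 5733	KT279697
Pachygrapsus_transversus	Ilha de Itamaraca, Brazil	CCDB 5734	KT279698
Uca_maracoani	Sirinhaem, Brazil	CCDB 2999	KT279699
Uca_uruguayensis	Rio Grande, Brazil	CCDB 5737	KT279703
Ucides_cordatus	Ipojuca, Brazil	CCDB 4467	KT279700
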