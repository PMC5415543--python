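(((((Aratus_pisonii:1,Armases_rubripes:1):1,(Goniopsis_cruentata:1,Pachygrapsus_transversus:1):1):1,(Neohelice_granulata:2,Cardisoma_guanhumi:2):1):1,(((Uca_maracoani:1,Uca_uruguayensis:1):1,Ocypode_quadrata:2):1,Ucides_cordatus:3):1):1,(Acanthocyclus_albatrossis:3,Halicarcinus_planatus:3):2);
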