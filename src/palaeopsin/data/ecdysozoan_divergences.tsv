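label	tip_a	tip_b	ci_young	ci_old
Pambdelurion_split	Pambdelurion	Pancrustacea	572	595
Opabinia_split	Opabinia	Pancrustacea	562	585
Anomalocaris_split	Anomalocaris	Pancrustacea	558	580
Fuxianhuia_split	Fuxianhuia	Pancrustacea	539	562
crown_Arthropoda	Chelicerata	Pancrustacea	519	540
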