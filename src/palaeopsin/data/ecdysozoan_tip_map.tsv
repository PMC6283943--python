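gene_tip	species	copy_id
Priapulida_ops1	Priapulida	ops1
Priapulida_ops2	Priapulida	ops2
Nematomorpha_ops1	Nematomorpha	ops1
Nematomorpha_ops2	Nematomorpha	ops2
Tardigrada_ops1	Tardigrada	ops1
Tardigrada_ops2	Tardigrada	ops2
Onychophora_ops1	Onychophora	ops1
Chelicerata_Rh7	Chelicerata	Rh7
Pancrustacea_Rh7	Pancrustacea	Rh7
Chelicerata_UVSWS	Chelicerata	UV/SWS
Pancrustacea_UV	Pancrustacea	UV
Pancrustacea_SWS	Pancrustacea	SWS
Chelicerata_MWS	Chelicerata	MWS
Myriapoda_MWS	Myriapoda	MWS
Pancrustacea_MWS	Pancrustacea	MWS
Chelicerata_LWS	Chelicerata	LWS
Myriapoda_LWS	Myriapoda	LWS
Pancrustacea_LWS	Pancrustacea	LWS
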