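species	genes
Priapulida	Rh7/UV/SWS/MWS/LWS
Nematomorpha	Rh7/UV/SWS/MWS/LWS
Tardigrada	Rh7/UV/SWS/MWS/LWS
Onychophora	Rh7/UV/SWS/MWS/LWS
Chelicerata	Rh7;UV/SWS;MWS;LWS
Myriapoda	MWS;LWS
Pancrustacea	Rh7;UV;SWS;MWS;LWS
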