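((Priapulida_ops1,Priapulida_ops2),((Nematomorpha_ops1,Nematomorpha_ops2),((Tardigrada_ops1,Tardigrada_ops2),(Onychophora_ops1,(((Chelicerata_Rh7,Pancrustacea_Rh7),(Chelicerata_UVSWS,(Pancrustacea_UV,Pancrustacea_SWS))),((Chelicerata_MWS,(Myriapoda_MWS,Pancrustacea_MWS)),(Chelicerata_LWS,(Myriapoda_LWS,Pancrustacea_LWS))))))));
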