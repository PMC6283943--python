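(Priapulida[&age=0],(Nematomorpha[&age=0],(Tardigrada[&age=0],(Onychophora[&age=0],((Kerygmachela[&age=518],Pambdelurion[&age=518])Kerygmachela_Pambdelurion[&age=545],(Opabinia[&age=508],(Anomalocaris[&age=514],(Fuxianhuia[&age=518],((Trilobita[&age=521],Chelicerata[&age=0])Trilobita_Chelicerata[&age=524],(Myriapoda[&age=0],Pancrustacea[&age=0])Mandibulata[&age=522])crown_Arthropoda[&age=529.5,ci={519,540}])Fuxianhuia_split[&age=550.5,ci={539,562}])Anomalocaris_split[&age=569,ci={558,580}])Opabinia_split[&age=573.5,ci={562,585}])Pambdelurion_split[&age=583.5,ci={572,595}])Panarthropoda[&age=590])Tardigrada_split[&age=597])Nematomorpha_split[&age=601])Ecdysozoa[&age=608];
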