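leaves_left	leaves_right	ci_young	ci_old
Rh7,UV,SWS	MWS,LWS	587	615
MWS	LWS	577	605
Rh7	UV,SWS	558	585
UV	SWS	509	527
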