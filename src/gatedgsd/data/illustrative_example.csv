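variant,analysis,population,endpoint,boundary,p_value
GSD,IA1,S,PFS,0.0036,0.0177
GSD,IA1,S,OS,0.0017,0.1205
GSD,IA1,F,PFS,0.0001,0.0008
GSD,IA1,F,OS,0.0001,0.0104
GSD,IA2,S,PFS,0.0088,0.0137
GSD,IA2,S,OS,0.0078,0.0502
GSD,IA2,F,PFS,0.0002,0.00022
GSD,IA2,F,OS,0.0001,0.0023
GSD,FA,S,OS,0.0120,0.0534
GSD,FA,F,OS,0.0002,0.0011
gGSD,IA1,S,PFS,0.0037,
gGSD,IA1,S,OS,0.0017,
gGSD,IA1,F,PFS,0.0039,0.0022
gGSD,IA1,F,OS,0.0024,0.0125
gGSD,IA2,S,PFS,0.0090,
gGSD,IA2,S,OS,0.0079,
gGSD,IA2,F,PFS,0.0089,
gGSD,IA2,F,OS,0.0088,0.0019
gGSD,FA,S,OS,0.0122,
gGSD,FA,F,OS,0.0119,
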