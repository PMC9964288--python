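park_id,coupling_index,coordination_index,coupling_coordination_index,level
QCP,0.992,0.804,0.893,9
YP,0.996,0.591,0.767,8
WRP,1,0.62,0.788,8
YWP,1,0.543,0.737,8
BTP,0.885,0.676,0.773,8
QEP,0.645,0.561,0.602,7
NWMC,0.985,0.392,0.621,7
CP,0.966,0.365,0.594,6
BP,0.966,0.332,0.567,6
LCP,0.972,0.273,0.515,6
UBP,0.413,0.112,0.215,3
WP,0.576,0.055,0.178,2
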