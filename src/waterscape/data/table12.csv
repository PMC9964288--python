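park_id,coupling_index,coordination_index,coupling_coordination_index,level
QCP,0.997,0.834,0.912,10
QEP,0.947,0.75,0.843,9
WRP,0.998,0.581,0.761,8
CP,0.821,0.63,0.719,8
YP,0.924,0.464,0.655,7
BTP,0.998,0.386,0.62,7
LCP,0.822,0.485,0.631,7
YWP,0.591,0.302,0.422,5
BP,0.955,0.19,0.426,5
WP,0.988,0.117,0.341,4
NWMC,0.341,0.167,0.239,3
UBP,0.262,0.287,0.274,3
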