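park_id,coupling_index,coordination_index,coupling_coordination_index,level
QCP,0.999,0.735,0.857,9
CP,0.93,0.725,0.821,9
WRP,0.998,0.583,0.763,8
BTP,0.91,0.7,0.798,8
LCP,0.922,0.549,0.711,8
YP,0.951,0.414,0.627,7
QEP,0.809,0.321,0.51,6
UBP,0.893,0.389,0.59,6
YWP,0.593,0.3,0.421,5
BP,0.857,0.276,0.486,5
NWMC,0.289,0.235,0.26,3
WP,0.506,0.073,0.192,2
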