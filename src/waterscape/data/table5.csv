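park_id,n_landscape,n_park,relative_evaluation_rate,landscape_emotional_value,park_emotional_value,relative_emotional_value
QCP,410,1376,29.8,7.2,3.5,2.1
QEP,26,84,30.1,2.3,3.3,0.7
YWP,10,28,35.7,7.8,4.5,1.7
NWMC,1,3,33.3,3.0,2.0,1.5
YP,7,28,25.0,2.4,1.4,1.7
CP,32,168,19.0,2.5,1.7,1.5
WP,3,30,23.3,0.6,1.5,0.4
BTP,225,630,31.0,5.9,2.1,2.8
BP,27,182,14.8,4.9,3.5,1.4
LCP,22,98,22.4,3.7,3.1,1.2
WRP,2,5,40.0,1.5,0.8,1.9
UBP,185,1822,10.2,2.4,2.8,0.9
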