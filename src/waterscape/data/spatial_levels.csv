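park_id,level
QEP,1
QCP,1
YP,2
WRP,2
YWP,2
BTP,2
NWMC,2
CP,3
BP,3
LCP,3
WP,4
UBP,4
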