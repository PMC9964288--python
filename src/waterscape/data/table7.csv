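park_id,thermal_mean,thermal_grade
CP,7.1583,high
UBP,6.9481,high
QEP,5.8863,high
QCP,3.3249,sub
BTP,2.1420,sub
BP,2.1073,sub
YP,1.9804,low
LCP,1.9525,low
WRP,1.6562,low
WP,1.6217,low
YWP,1.4416,low
NWMC,1.3719,low
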