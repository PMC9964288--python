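park_id,horizontal,vertical,three_dimensional
QEP,0.5944,0.4047,0.6429
QCP,0.5039,0.4816,0.6340
YP,0.5135,0.4385,0.5985
WRP,0.4638,0.4165,0.6643
YWP,0.4519,0.4165,0.6573
BTP,0.4412,0.4367,0.5995
NWMC,0.5057,0.4691,0.4932
CP,0.3321,0.4230,0.6987
BP,0.3894,0.4545,0.6036
LCP,0.4353,0.4456,0.5567
WP,0.3688,0.4635,0.5767
UBP,0.3316,0.4921,0.5620
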