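park_id,coupling_index,coordination_index,coupling_coordination_index,level,label
QCP,0.995,0.791,0.887,9,Good coordination
WRP,0.998,0.595,0.770,8,Moderate coordination
BTP,0.898,0.587,0.726,8,Moderate coordination
CP,0.867,0.573,0.705,8,Moderate coordination
QEP,0.746,0.544,0.637,7,Mild coordination
YP,0.946,0.489,0.680,7,Mild coordination
LCP,0.865,0.435,0.614,7,Mild coordination
YWP,0.677,0.382,0.508,6,Poor coordination
BP,0.901,0.266,0.490,5,Near maladjustment
NWMC,0.432,0.265,0.338,4,Mild maladjustment
UBP,0.405,0.263,0.326,4,Mild maladjustment
WP,0.628,0.082,0.226,3,Moderate maladjustment
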