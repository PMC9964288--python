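park_id,C1,C2,C3,C4,C5,C6,C7,C8,C9,C10,C11,C12
QEP,0.8334,0.8863,0.4344,0.2235,0.2639,0.5455,0.0033,0.8061,0.2237,0.7318,0.7624,0.8536
QCP,0.7419,0.8454,0.2459,0.1823,0.4226,0.6363,0.0185,0.8488,0.2648,0.8711,0.5606,0.8394
YP,0.7304,0.7863,0.3584,0.1790,0.4545,0.4226,0.0739,0.8032,0.3048,0.6742,0.6126,0.8024
WRP,0.6497,0.4525,0.5687,0.1844,0.7142,0.1188,0.0245,0.8085,0.2941,0.8331,0.7043,0.8258
YWP,0.7216,0.6012,0.414,0.0708,0.5000,0.3330,0.0080,0.8250,0.3226,0.6942,0.7714,0.8409
BTP,0.6817,0.3113,0.5361,0.2357,0.2500,0.6234,0.0172,0.8562,0.3514,0.6804,0.5140,0.8520
NWMC,0.6812,0.7063,0.4544,0.1807,0.5454,0.3928,0.0031,0.9351,0.3831,0.1743,0.4820,0.9332
CP,0.5214,0.4067,0.3344,0.0660,0.3636,0.4824,0.0206,0.8254,0.2935,0.9015,0.7604,0.8394
BP,0.5268,0.3349,0.5319,0.1640,0.5714,0.3376,0.0622,0.8468,0.3132,0.6221,0.6419,0.8373
LCP,0.3855,0.4874,0.58369,0.2845,0.7000,0.1911,0.0813,0.8100,0.1426,0.4438,0.8309,0.8095
WP,0.1942,0.0654,0.469,0.7467,0.3000,0.6270,0.0648,0.8622,0.7023,0.5627,0.1903,0.8513
UBP,0.0533,0.0656,0.4399,0.7677,0.7142,0.4049,-0.0070,0.8564,0.5703,0.5307,0.2732,0.8737
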