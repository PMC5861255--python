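oligo,synthetic_01,synthetic_02,synthetic_03,synthetic_04,synthetic_05,synthetic_06,synthetic_07,synthetic_08,synthetic_09
AAA,-0.9118,-0.6178,0.2443,0.9903,-1.5811,1.267,0.8292,-0.5759,-1.5869
AAC,-1.8403,-0.7527,-1.5264,-0.9376,-0.4851,1.2574,-0.2514,-0.5004,0.7382
AAG,0.1972,-1.2973,-1.0296,-1.5721,-1.9801,1.2852,-0.6396,-1.0663,1.9076
AAT,-1.4405,1.7302,-1.8892,-1.7799,-1.832,-1.6662,-0.6474,1.4737,-0.1069
ACA,-0.3067,1.4856,0.7461,-0.741,-1.9681,0.0449,1.4939,-1.879,0.1833
ACC,1.3301,-1.4916,0.329,0.2163,1.8006,-1.0532,1.7808,-1.1997,-1.7484
ACG,-1.149,1.3011,-1.1359,1.1254,-1.0688,-0.0697,-1.2919,-1.9725,1.1842
ACT,0.4518,0.7985,1.741,1.5356,-0.9344,1.9094,-0.9676,-1.575,0.2446
AGA,0.176,-0.5352,0.7941,0.833,0.819,-0.4309,-0.6739,1.355,-0.5083
AGC,-0.1077,0.6655,-1.6706,0.915,1.7872,0.4809,-0.2985,1.7484,-1.8072
AGG,-1.647,-0.464,-0.9058,0.573,-0.3115,1.4711,1.3782,0.0033,-1.323
AGT,0.256,-1.6242,-1.9139,-1.7661,-0.5586,1.4577,1.7923,1.0731,-1.0705
ATA,-0.6535,-1.6483,0.014,-0.7806,-0.3144,0.8845,-0.9673,0.531,0.1207
ATC,-0.3551,0.7263,0.6535,1.9481,1.084,-0.917,1.0418,-1.8145,0.9848
ATG,1.8952,0.7929,-1.8142,0.0514,0.2125,-1.8205,-1.1219,-1.6099,-0.0085
ATT,-1.0252,-0.7314,-0.016,1.7217,-0.2864,-1.3836,0.3698,-0.7877,-1.5783
CAA,0.7405,-1.1579,-1.8085,0.0839,1.1726,-0.4886,1.0173,-0.6169,-0.6636
CAC,1.3664,-1.1033,1.5688,0.275,0.3233,1.7204,0.5127,1.4081,0.9549
CAG,0.9591,0.6997,-1.9681,1.6132,-1.42,-1.9626,0.4805,0.2924,1.0901
CAT,1.7664,0.0209,-1.6183,1.5281,-0.0725,-0.0585,-0.9881,-1.9438,0.3866
CCA,-0.8513,-0.9836,0.1161,-1.2126,1.4207,0.0529,-1.629,-0.3328,1.0001
CCC,-1.8489,-0.1334,0.5137,0.7173,-0.0314,-0.7376,1.4618,-1.2447,1.0841
CCG,1.181,0.4837,0.6946,0.7695,1.0007,1.4923,1.184,-0.154,-1.2654
CCT,1.5853,1.5934,0.7519,-1.8119,-0.8008,0.6615,1.5587,-0.0782,0.3414
CGA,1.8808,-0.2511,-1.6944,-1.4968,0.1514,-1.6382,0.2305,-1.3505,1.7417
CGC,0.9298,0.2889,1.147,-1.0093,0.2764,1.3699,-0.6725,1.7689,0.1237
CGG,-1.7809,-1.5517,-0.2796,-0.4174,0.4164,1.9451,-1.4396,1.9634,0.0931
CGT,-0.4001,-0.0676,1.731,0.2273,1.8256,-1.4676,-0.2128,-0.6237,-1.7275
CTA,-0.4071,-1.235,0.6476,-0.7589,0.7608,-1.2695,-1.2833,0.3435,-0.2944
CTC,-1.4366,0.3776,0.5858,-0.3796,-1.3705,-0.3803,-0.6733,-0.4605,1.7679
CTG,-0.4551,1.1094,1.7319,0.3125,1.8507,-0.753,-1.4489,1.8459,1.7212
CTT,-0.1857,1.3369,-0.4162,-0.4571,-0.6101,-1.4404,0.2425,1.9814,1.212
GAA,-1.7793,1.1505,0.9214,-1.7395,-0.2382,1.4273,0.4688,-1.9797,-1.0836
GAC,0.196,-0.7044,1.2207,0.9857,-1.9866,0.3678,-1.8136,0.4895,0.3567
GAG,1.1415,-1.5423,1.9685,-0.8376,-0.8136,-0.2083,0.2398,1.9867,1.7448
GAT,-0.9106,-1.2378,-0.6026,-1.1129,0.2162,-1.2539,-0.0105,-1.2802,-1.0631
GCA,-1.7835,1.305,0.71,0.2192,-1.4306,-1.4471,-1.5821,0.3735,0.0393
GCC,1.4892,-1.9774,1.0367,-1.8779,-1.4425,1.0464,-0.8356,1.6512,0.3828
GCG,-1.0469,1.1412,1.7691,1.7518,-1.09,-0.8874,0.1413,-0.6997,1.68
GCT,-0.431,-1.6893,-1.9697,-1.1801,-1.5595,1.17,1.6678,-0.3647,-1.4551
GGA,-0.3352,0.8147,1.3412,-1.7778,-1.3911,0.0,-1.0258,0.8308,1.7389
GGC,0.3507,1.4984,-0.173,0.8424,1.527,1.4532,-1.1375,1.1975,-1.1358
GGG,-0.7301,0.5657,-1.034,1.4125,-0.8034,-0.225,-1.2769,-0.9523,1.394
GGT,-0.9497,-1.6623,1.2873,-0.4533,1.5511,0.5526,0.1876,0.2067,-1.0455
GTA,-0.0639,-1.0965,-1.5399,1.6643,-1.1788,1.8606,-0.6952,1.9406,-0.0832
GTC,0.2217,-1.6954,-0.4094,-1.4581,1.014,0.0621,0.3918,-0.0746,0.1607
GTG,-0.163,1.2788,1.4729,-1.89,1.5895,-1.4421,-0.298,-0.178,-1.5
GTT,-1.9874,1.0991,-1.0902,-0.9663,1.8683,-1.1755,-1.2545,-1.6367,-0.8191
TAA,-0.1115,1.6694,1.3599,0.9333,0.8644,0.2644,-0.0009,-1.8145,1.6574
TAC,-0.654,-0.8725,-1.3455,1.6586,-1.9233,-1.3162,0.0828,1.9061,0.5294
TAG,0.2749,-0.8213,0.9737,-1.2598,-0.4225,-1.3034,1.2731,-1.346,-0.5147
TAT,-1.8048,1.6481,-1.6939,-0.8114,0.1363,-0.509,-1.3359,-0.4335,-1.7014
TCA,-0.8524,-1.2493,1.9239,1.4984,1.7555,-1.0075,-1.889,0.58,1.1845
TCC,0.8567,-0.5416,-0.2258,1.6866,-0.5446,-0.2861,-1.9365,0.2617,0.561
TCG,-0.3215,-1.2348,1.3009,-0.3009,0.6051,0.4192,-0.2662,1.653,-1.7475
TCT,-0.1512,1.2733,-1.8538,-1.7545,-0.0873,1.1197,-0.3384,-0.4447,1.0623
TGA,1.9042,0.5765,1.1218,-0.5008,-0.2972,-1.8664,-0.548,0.2615,-1.874
TGC,-1.6265,1.6518,0.0319,0.5306,0.7196,-1.1643,-1.2341,1.1802,1.5136
TGG,1.066,-1.8619,0.0035,0.3333,-0.0476,0.0816,-1.4758,1.0565,-1.311
TGT,-1.4934,-1.5837,0.5694,-1.1617,-0.5791,0.7359,-0.6663,1.9057,-1.7018
TTA,-0.9572,-0.6723,-0.5986,1.1977,0.7381,-1.7422,-1.5578,0.0027,-1.883
TTC,-1.1554,-0.5208,0.3982,0.1645,-1.5744,-1.972,-0.6165,-0.4355,0.1372
TTG,-1.209,-0.8642,1.436,-0.9644,0.7318,0.5819,0.5627,1.2771,0.548
TTT,-1.7827,-1.921,0.7482,1.0391,0.6226,-1.6462,-0.0114,1.9674,0.9594
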