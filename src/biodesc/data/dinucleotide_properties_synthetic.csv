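oligo,synthetic_01,synthetic_02,synthetic_03,synthetic_04,synthetic_05,synthetic_06,synthetic_07,synthetic_08,synthetic_09,synthetic_10,synthetic_11,synthetic_12,synthetic_13,synthetic_14,synthetic_15,synthetic_16,synthetic_17,synthetic_18,synthetic_19,synthetic_20,synthetic_21,synthetic_22,synthetic_23,synthetic_24,synthetic_25,synthetic_26,synthetic_27,synthetic_28,synthetic_29,synthetic_30,synthetic_31,synthetic_32
AA,1.4349,1.1288,-0.733,-0.7796,-1.5442,0.3477,-1.4816,-1.0762,-0.9077,1.6637,1.1112,-0.3384,-1.5878,-0.5256,1.8782,-1.4917,1.7538,0.6606,0.4221,0.3563,-0.9949,-0.0624,1.2182,1.586,-1.3645,-0.1281,-1.6906,0.9265,1.3029,1.2498,-0.6672,-1.156
AC,1.9631,0.2,1.6846,1.642,0.6763,-1.4495,-1.6164,-1.2938,1.4041,-0.6769,-1.8333,0.7819,1.8107,-0.8764,-0.5066,-1.8076,-1.4773,-1.1486,-0.1464,-0.1578,-0.7666,1.7163,-0.3986,0.8515,1.3757,-1.7895,1.6627,-0.5308,1.2807,0.4936,-1.2967,-1.8137
AG,-1.7557,-0.8965,1.9879,0.76,-1.9391,0.2069,1.687,0.243,0.3393,-0.3525,-0.9022,0.7158,0.9038,-0.3936,0.8459,-1.2873,-1.5685,-1.7334,-0.5345,-1.9825,-0.4571,-0.8887,0.7592,0.5108,0.7576,1.3837,1.9501,0.9137,1.7678,1.1588,0.1023,-1.7948
AT,-1.0492,-0.2133,0.8108,1.5854,0.843,-0.6842,1.4972,1.205,0.2479,-1.2405,1.8955,1.1061,-0.5067,-0.3475,-0.1632,1.7571,-0.3304,1.7122,-1.3372,-1.044,0.0552,1.9365,-0.1946,1.0298,-0.1471,1.1458,1.4363,0.978,1.3632,-0.5294,1.9912,0.0393
CA,-0.75,-1.1714,-0.4641,-0.9797,0.8204,-1.9931,1.0014,0.8508,-1.1212,0.4568,0.7827,0.9077,-1.0979,0.6136,0.8826,-1.863,-0.0652,0.2922,1.4865,-1.8255,-1.2547,0.0944,0.1818,-1.6535,0.909,0.2802,-1.6601,-0.5395,-1.2159,1.9182,-1.8233,-1.685
CC,-1.7393,1.4719,-0.7518,-0.3622,0.5807,-1.1944,-0.7154,-1.2841,-0.1171,-1.0028,-0.329,-1.8848,-1.0796,1.4448,-0.5665,-1.8942,1.904,1.3006,0.1209,-0.3152,0.9965,0.1434,1.5427,-1.1549,-0.689,-0.2101,1.9767,1.0229,0.3707,-1.221,-1.1156,-1.5723
CG,-1.0074,-0.9841,-1.7379,1.6826,0.3657,0.5255,1.1163,-1.565,0.4612,0.6616,0.874,-0.9748,1.0767,0.2075,1.9546,1.3303,0.2555,-0.5164,-1.0314,-1.3778,1.9584,-0.7328,0.7516,-0.1021,-0.6493,-0.9487,1.6,0.398,-1.9574,0.1453,-1.526,1.007
CT,0.1637,1.6412,-0.5589,-1.4126,1.9585,1.8591,-0.983,0.5868,1.3256,1.9639,1.3201,-0.6865,0.8809,-1.5358,0.2035,0.8327,1.2382,0.6637,0.4387,1.9865,0.5292,1.7305,-0.3693,1.1488,1.4695,-1.7237,-0.5241,-0.466,-1.6571,-0.2856,-0.7805,-0.513
GA,0.8664,-0.391,-1.9915,-0.462,1.0304,-1.0497,1.5512,-0.2304,-0.6609,1.4736,1.2983,1.4781,0.4728,0.9019,-0.3635,0.9008,-1.4685,-1.6197,-1.5309,-1.6157,1.0996,1.2516,1.4306,-1.8963,1.6072,1.3228,0.6004,0.92,1.9327,-0.4925,1.7962,0.293
GC,-1.8518,0.8544,-1.1654,-1.3482,1.7339,-0.9132,-1.568,1.5697,-0.2463,-1.2261,0.8467,1.9451,1.9852,0.3906,-0.5453,1.1398,1.9474,-0.3746,1.9422,-0.1956,-1.1521,1.2785,0.8877,-1.883,-1.0658,1.2548,-0.7971,0.3829,1.2761,-0.0933,0.7975,-1.9545
GG,1.3407,1.4118,1.0727,-1.0622,0.1183,-0.536,1.7289,-0.6503,-0.7517,-1.5942,-0.7461,-1.3676,-0.7384,-0.4086,1.7767,-0.6026,1.333,0.4168,1.7613,0.7823,1.4611,1.3192,-0.7196,-0.35,0.8711,-1.783,1.8591,0.8517,0.0718,1.1882,-0.1714,1.267
GT,-0.0779,0.0987,0.8395,-0.9093,-0.4819,1.2363,-0.6535,-1.5656,-1.0504,0.7314,-0.518,0.9973,0.5393,-1.1768,-0.8261,0.6721,0.1981,-1.1252,0.311,0.054,-0.1202,-0.9202,-0.8544,1.2987,-1.9403,0.8783,1.9083,0.1408,0.1616,-1.4115,1.7315,-1.0204
TA,0.7479,-1.202,0.722,1.4992,1.6313,0.8837,-0.6064,0.3177,-0.941,-1.0293,-0.3633,0.4712,0.3608,1.8016,-1.5087,1.5791,0.6247,-1.5942,1.6359,1.6551,-0.3584,1.7447,-0.144,0.1033,-1.2068,0.4153,1.4258,1.9652,0.6989,-1.7787,0.087,1.95
TC,0.2816,0.9034,-0.0331,-1.3075,-0.5993,1.3067,0.5398,-0.9639,1.8236,1.0353,0.1858,0.0084,-0.2964,-1.8796,0.96,0.9348,-1.0343,1.8376,0.0443,0.3416,-1.4397,-1.7657,1.1788,1.1151,-0.8655,-0.7374,0.7657,0.115,0.5674,-1.8785,0.321,-1.586
TG,0.7775,1.5417,-1.6305,0.6312,1.2847,-1.2794,-0.1308,-1.8595,-1.4214,-0.2641,-1.6403,0.5378,-1.6885,0.0102,0.5965,1.027,0.8945,1.9375,1.783,-1.4124,0.0455,-0.1955,1.886,-1.7714,-0.9343,-0.1064,-1.7765,1.57,1.8574,1.1557,-1.3284,1.8957
TT,-0.2143,0.822,-1.5715,-1.4712,-1.974,1.7111,0.3736,-0.0778,0.1719,-1.2832,1.1522,1.3728,0.7114,-1.9263,-1.0339,-1.9675,-1.4435,-1.7515,-0.5058,-1.7026,0.4747,-0.4879,0.4884,1.4507,-1.8933,-0.7324,-1.2452,-1.1041,0.4056,1.5388,1.0658,-0.3557
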