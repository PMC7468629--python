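locus,mp,pd,pic,pe,tpi,ho,he,hwe_p,insertion,deletion
rs3029066,0.5912,0.4088,0.2197,0.0468,0.6715,0.2554,0.2515,0.8400,0.1473,0.8527
rs5891435,0.3913,0.6087,0.3612,0.1685,0.9568,0.4774,0.4736,0.8632,0.3841,0.6159
rs3045215,0.3828,0.6172,0.3590,0.1430,0.8993,0.4440,0.4693,0.2522,0.3752,0.6248
rs3839348,0.3900,0.6100,0.3708,0.1989,1.0262,0.5128,0.4921,0.3504,0.5648,0.4352
rs3831885,0.3974,0.6026,0.3554,0.1591,0.9357,0.4656,0.4626,0.8924,0.3625,0.6375
rs10533439,0.5706,0.4294,0.2367,0.0435,0.6628,0.2456,0.2745,0.1432,0.1640,0.8360
rs34477782,0.4892,0.5108,0.2851,0.0722,0.7355,0.3202,0.3447,0.2459,0.7790,0.2210
rs4647655,0.3841,0.6159,0.3628,0.1607,0.9391,0.4676,0.4767,0.6808,0.6090,0.3910
rs3028822,0.4322,0.5678,0.3224,0.1007,0.8028,0.3772,0.4044,0.2109,0.2809,0.7191
rs2307783,0.4239,0.5761,0.3283,0.1074,0.8183,0.3890,0.4145,0.2431,0.7073,0.2927
rs10555216,0.3701,0.6299,0.3701,0.1607,0.9391,0.4676,0.4908,0.2957,0.5697,0.4303
rs10538061,0.6831,0.3169,0.1742,0.0210,0.5988,0.1650,0.1929,0.1105,0.8919,0.1081
rs10569275,0.5651,0.4349,0.2386,0.0474,0.6733,0.2574,0.2772,0.3181,0.1660,0.8340
rs35434967,0.5731,0.4269,0.2338,0.0454,0.6680,0.2515,0.2706,0.3324,0.8389,0.1611
rs3840222,0.6167,0.3833,0.2091,0.0343,0.6378,0.2161,0.2375,0.2577,0.8625,0.1375
rs3840794,0.4951,0.5049,0.2814,0.0696,0.7292,0.3143,0.3391,0.2372,0.7839,0.2161
rs11273905,0.3539,0.6461,0.3717,0.1334,0.8776,0.4303,0.4940,0.0040,0.5570,0.4430
rs36038238,0.4073,0.5927,0.3429,0.1321,0.8746,0.4283,0.4400,0.5955,0.6739,0.3261
rs34921138,0.6451,0.3549,0.1899,0.0315,0.6300,0.2063,0.2127,0.7252,0.8792,0.1208
rs146391383,0.7848,0.2152,0.1228,0.0081,0.5545,0.0982,0.1316,0.0260,0.9293,0.0707
rs3830479,0.6287,0.3713,0.2102,0.0252,0.6118,0.1827,0.2389,0.0030,0.1385,0.8615
rs10534050,0.3697,0.6303,0.3737,0.1733,0.9677,0.4833,0.4978,0.5116,0.5363,0.4637
rs5788637,0.4452,0.5548,0.3132,0.0891,0.7759,0.3556,0.3892,0.1198,0.7358,0.2642
rs147090496,0.3807,0.6193,0.3597,0.1416,0.8961,0.4420,0.4708,0.1939,0.3782,0.6218
rs16432,0.5346,0.4654,0.2592,0.0495,0.6787,0.2633,0.3064,0.0349,0.1886,0.8114
rs3835409,0.3830,0.6170,0.3527,0.1144,0.8344,0.4008,0.4576,0.0101,0.6464,0.3536
rs4147539,0.6016,0.3984,0.2145,0.0422,0.6593,0.2417,0.2445,0.8796,0.8576,0.1424
rs2307840,0.4422,0.5578,0.3203,0.1218,0.8512,0.4126,0.4009,0.5925,0.7230,0.2770
rs57406754,0.3707,0.6293,0.3736,0.1749,0.9714,0.4853,0.4977,0.5747,0.5373,0.4627
rs3216799,0.6703,0.3297,0.1742,0.0278,0.6192,0.1925,0.1929,0.9811,0.1081,0.8919
rs3044252,0.6392,0.3608,0.1922,0.0337,0.6363,0.2141,0.2156,0.9348,0.1228,0.8772
rs5896844,0.8992,0.1008,0.0538,0.0022,0.5258,0.0491,0.0554,0.5351,0.0285,0.9715
rs10580743,0.5672,0.4328,0.2347,0.0531,0.6878,0.2731,0.2719,0.9517,0.1621,0.8379
rs3842715,0.3798,0.6202,0.3699,0.1782,0.9788,0.4892,0.4905,0.9538,0.4293,0.5707
rs3034941,0.3841,0.6159,0.3628,0.1607,0.9391,0.4676,0.4767,0.6808,0.3910,0.6090
rs5788207,0.3991,0.6009,0.3748,0.2272,1.0923,0.5422,0.5002,0.0576,0.4872,0.5128
rs145119206,0.3923,0.6077,0.3539,0.1430,0.8993,0.4440,0.4599,0.4726,0.6424,0.3576
rs3047538,0.6862,0.3138,0.1717,0.0210,0.5988,0.1650,0.1899,0.1532,0.8939,0.1061
rs3033760,0.4451,0.5549,0.3155,0.1062,0.8157,0.3870,0.3929,0.7864,0.7318,0.2682
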