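T_K,x2,P_Pa,dP_Pa,gamma1,gamma2,GE_J_mol
278.15,0.0309,1485,3,1.0012,2.9938,81
278.15,0.1004,1425,22,1.0120,2.5666,244
278.15,0.2031,1303,1,1.0488,2.1015,437
278.15,0.3294,1195,1,1.1308,1.7073,598
278.15,0.4351,1107,-2,1.2377,1.4756,670
278.15,0.5233,1024,-13,1.3622,1.3297,686
278.15,0.6307,944,6,1.5749,1.1958,649
278.15,0.7188,849,13,1.8228,1.1146,571
278.15,0.8182,661,-16,2.2277,1.0494,428
278.15,0.8670,576,7,2.4999,1.0271,335
278.15,0.9382,347,-5,3.0297,1.0061,172
278.15,0.9882,149,16,3.5396,1.0002,35
283.15,0.0310,2128,20,1.0012,2.9499,82
283.15,0.1006,2007,14,1.0119,2.5340,245
283.15,0.2032,1865,19,1.0482,2.0801,439
283.15,0.3295,1684,-6,1.1293,1.6938,601
283.15,0.4352,1569,1,1.2347,1.4666,673
283.15,0.5234,1451,-13,1.3573,1.3233,688
283.15,0.6308,1323,2,1.5661,1.1918,650
283.15,0.7189,1176,2,1.8084,1.1121,572
283.15,0.8182,940,-5,2.2020,1.0483,429
283.15,0.8670,808,17,2.4652,1.0264,336
283.15,0.9382,471,-14,2.9741,1.0060,172
283.15,0.9882,183,3,3.4600,1.0002,35
288.15,0.0313,3010,22,1.0012,2.9026,82
288.15,0.1006,2838,13,1.0117,2.4997,246
288.15,0.2032,2622,7,1.0476,2.0570,440
288.15,0.3297,2398,7,1.1277,1.6793,602
288.15,0.4353,2205,-11,1.2314,1.4569,674
288.15,0.5235,2056,-10,1.3519,1.3165,689
288.15,0.6309,1859,-1,1.5565,1.1875,651
288.15,0.7190,1655,6,1.7930,1.1095,572
288.15,0.8183,1329,6,2.1748,1.0471,428
288.15,0.8671,1112,7,2.4285,1.0257,335
288.15,0.9382,657,-17,2.9160,1.0058,171
288.15,0.9882,253,3,3.3775,1.0002,35
293.15,0.0316,4112,12,1.0012,2.8844,84
293.15,0.1007,3892,15,1.0119,2.4806,249
293.15,0.2033,3574,-15,1.0480,2.0388,444
293.15,0.3299,3264,-17,1.1283,1.6638,607
293.15,0.4354,3010,-28,1.2315,1.4448,677
293.15,0.5236,2828,-2,1.3506,1.3070,691
293.15,0.6310,2564,22,1.5514,1.1811,651
293.15,0.7191,2274,28,1.7811,1.1052,570
293.15,0.8184,1800,8,2.1471,1.0450,426
293.15,0.8672,1469,-22,2.3875,1.0245,333
293.15,0.9383,896,-10,2.8430,1.0055,170
293.15,0.9882,321,-16,3.2674,1.0002,34
298.15,0.0321,5654,29,1.0012,2.8630,87
298.15,0.1009,5320,-2,1.0121,2.4607,252
298.15,0.2035,4936,6,1.0484,2.0208,448
298.15,0.3302,4481,-25,1.1288,1.6490,611
298.15,0.4356,4154,-18,1.2312,1.4336,680
298.15,0.5238,3894,12,1.3491,1.2983,692
298.15,0.6312,3492,12,1.5461,1.1752,651
298.15,0.7193,3078,11,1.7695,1.1014,569
298.15,0.8185,2446,9,2.1213,1.0431,424
298.15,0.8673,2003,-21,2.3501,1.0234,331
298.15,0.9384,1221,-5,2.7782,1.0052,168
298.15,0.9882,475,10,3.1715,1.0002,34
303.15,0.0329,7621,-14,1.0013,2.8303,89
303.15,0.1013,7215,-10,1.0121,2.4362,255
303.15,0.2038,6699,8,1.0484,2.0025,451
303.15,0.3307,6105,-7,1.1285,1.6356,614
303.15,0.4358,5640,-17,1.2298,1.4243,683
303.15,0.5241,5248,-10,1.3462,1.2914,694
303.15,0.6314,4713,9,1.5397,1.1707,652
303.15,0.7195,4153,16,1.7580,1.0986,569
303.15,0.8187,3313,38,2.0988,1.0418,423
303.15,0.8675,2676,-37,2.3189,1.0226,330
303.15,0.9384,1623,-17,2.7274,1.0050,168
303.15,0.9883,633,7,3.0988,1.0002,34
308.15,0.0325,10218,-11,1.0013,2.8076,89
308.15,0.1017,9658,-16,1.0122,2.4119,257
308.15,0.2041,8951,-10,1.0485,1.9839,455
308.15,0.3315,8170,-11,1.1286,1.6216,618
308.15,0.4362,7557,-11,1.2288,1.4145,685
308.15,0.5245,7054,27,1.3437,1.2841,696
308.15,0.6318,6249,-27,1.5338,1.1660,652
308.15,0.7199,5537,30,1.7469,1.0956,569
308.15,0.8189,4353,7,2.0764,1.0404,422
308.15,0.8677,3589,-4,2.2877,1.0218,329
308.15,0.9386,2140,-30,2.6763,1.0048,167
308.15,0.9883,871,28,3.0260,1.0002,34
313.15,0.0338,13490,-48,1.0014,2.7686,93
313.15,0.1015,12790,-27,1.0122,2.3878,258
313.15,0.2039,11878,11,1.0481,1.9658,456
313.15,0.3310,10824,-2,1.1274,1.6093,619
313.15,0.4368,9977,-20,1.2274,1.4039,686
313.15,0.5251,9254,-16,1.3408,1.2763,696
313.15,0.6324,8269,10,1.5272,1.1610,651
313.15,0.7204,7246,21,1.7346,1.0924,567
313.15,0.8193,5721,44,2.0524,1.0389,420
313.15,0.8680,4656,-24,2.2547,1.0210,326
313.15,0.9387,2780,-36,2.6232,1.0046,165
313.15,0.9883,1072,-26,2.9512,1.0002,33
318.15,0.0363,17673,-13,1.0016,2.7299,100
318.15,0.1024,16765,-2,1.0124,2.3622,262
318.15,0.2045,15507,-19,1.0485,1.9459,460
318.15,0.3322,14127,-25,1.1281,1.5933,622
318.15,0.4365,13040,-31,1.2259,1.3944,687
318.15,0.5247,12103,-6,1.3373,1.2693,696
318.15,0.6319,10780,15,1.5195,1.1565,650
318.15,0.7199,9481,84,1.7204,1.0896,565
318.15,0.8198,7322,-12,2.0291,1.0373,417
318.15,0.8684,5993,-37,2.2218,1.0200,323
318.15,0.9389,3592,-26,2.5692,1.0044,163
318.15,0.9883,1432,7,2.8747,1.0002,33
323.15,0.0410,22785,-29,1.0020,2.6720,113
323.15,0.1037,21678,-11,1.0127,2.3316,266
323.15,0.2055,20080,-7,1.0487,1.9245,463
323.15,0.3341,18256,-32,1.1287,1.5768,625
323.15,0.4375,16849,-38,1.2249,1.3840,689
323.15,0.5257,15679,54,1.3349,1.2616,696
323.15,0.6328,13851,-11,1.5135,1.1516,649
323.15,0.7206,12092,22,1.7092,1.0867,563
323.15,0.8204,9415,32,2.0078,1.0358,414
323.15,0.8689,7677,-23,2.1926,1.0192,321
323.15,0.9392,4569,-50,2.5224,1.0042,162
323.15,0.9883,1889,38,2.8096,1.0002,33
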