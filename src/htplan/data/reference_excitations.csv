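tumor_radius_mm,antenna,power_W,phase_deg
2,1,0.3113,9.1212
2,2,2.8172,-55.0652
2,3,3.1238,7.5346
2,4,0.7207,122.8282
2,5,0.0015,155.1581
2,6,0.0252,82.6938
2,7,0.3572,30.1722
2,8,0.6431,0
4,1,0.3202,9.8917
4,2,2.8224,-53.5573
4,3,3.1074,8.0062
4,4,0.6914,124.1266
4,5,0.0014,159.7430
4,6,0.0257,77.6330
4,7,0.3668,28.1556
4,8,0.6647,0
6,1,0.3491,12.0320
6,2,2.8912,-51.2217
6,3,2.9268,10.5009
6,4,0.6478,128.7051
6,5,0.0011,179.4337
6,6,0.0243,70.5049
6,7,0.3954,25.5423
6,8,0.7643,0
8,1,0.3932,12.6731
8,2,3.2524,-53.2903
8,3,2.6419,9.9976
8,4,0.5701,135.6660
8,5,0.0020,-147.9632
8,6,0.0105,61.6180
8,7,0.3104,26.5520
8,8,0.8195,0
10,1,0.4054,14.6487
10,2,3.7182,-52.4283
10,3,2.4654,8.4417
10,4,0.4516,140.2195
10,5,0.0036,-125.5640
10,6,0.0066,12.1489
10,7,0.1896,18.0303
10,8,0.7596,0
12,1,0.3320,23.0597
12,2,4.3765,-43.1907
12,3,2.4697,11.1388
12,4,0.2764,148.3518
12,5,0.0077,-99.0500
12,6,0.0456,-37.1462
12,7,0.0842,-42.1068
12,8,0.4079,0
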