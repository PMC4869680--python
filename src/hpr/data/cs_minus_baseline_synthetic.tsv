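time_s	value
0.000000	0.0000000000
0.100000	0.0199915030
0.200000	0.1144156017
0.300000	0.2758379749
0.400000	0.4661234886
0.500000	0.6473412322
0.600000	0.7927122715
0.700000	0.8881808880
0.800000	0.9301906586
0.900000	0.9224355211
1.000000	0.8728265916
1.100000	0.7911215422
1.200000	0.6872801177
1.300000	0.5704472791
1.400000	0.4484162771
1.500000	0.3274276271
1.600000	0.2121845109
1.700000	0.1059945139
1.800000	0.0109745087
1.900000	-0.0717227497
2.000000	-0.1416855944
2.100000	-0.1990380981
2.200000	-0.2442593919
2.300000	-0.2780305275
2.400000	-0.3011096975
2.500000	-0.3142357815
2.600000	-0.3180598940
2.700000	-0.3131043582
2.800000	-0.2997480387
2.900000	-0.2782361067
3.000000	-0.2487111380
3.100000	-0.2112611348
3.200000	-0.1659788375
3.300000	-0.1130258120
3.400000	-0.0526944426
3.500000	0.0145387543
3.600000	0.0879741465
3.700000	0.1666684947
3.800000	0.2494352467
3.900000	0.3348658699
4.000000	0.4213705080
4.100000	0.5072345478
4.200000	0.5906864207
4.300000	0.6699712259
4.400000	0.7434245833
4.500000	0.8095414607
4.600000	0.8670354860
4.700000	0.9148853280
4.800000	0.9523659740
4.900000	0.9790640172
5.000000	0.9948772633
5.100000	1.0000000000
5.200000	0.9948960641
5.300000	0.9802623764
5.400000	0.9569858775
5.500000	0.9260968249
5.600000	0.8887212254
5.700000	0.8460348443
5.800000	0.7992207826
5.900000	0.7494321249
6.000000	0.6977606461
6.100000	0.6452120912
6.200000	0.5926881157
6.300000	0.5409746180
6.400000	0.4907359284
6.500000	0.4425141211
6.600000	0.3967326071
6.700000	0.3537031169
6.800000	0.3136351927
6.900000	0.2766473648
7.000000	0.2427792716
7.100000	0.2120040888
7.200000	0.1842407469
7.300000	0.1593655308
7.400000	0.1372227685
7.500000	0.1176344109
7.600000	0.1004083956
7.700000	0.0853457574
7.800000	0.0722465069
7.900000	0.0609143412
8.000000	0.0511602817
8.100000	0.0428053539
8.200000	0.0356824324
8.300000	0.0296373778
8.400000	0.0245295888
8.500000	0.0202320838
8.600000	0.0166312178
8.700000	0.0136261257
8.800000	0.0111279733
8.900000	0.0090590822
9.000000	0.0073519838
9.100000	0.0059484468
9.200000	0.0047985113
9.300000	0.0038595553
9.400000	0.0030954120
9.500000	0.0024755485
9.600000	0.0019743140
9.700000	0.0015702598
9.800000	0.0012455312
9.900000	0.0009853293
10.000000	0.0007774388
10.100000	0.0006118175
10.200000	0.0004802413
10.300000	0.0003760005
10.400000	0.0002936405
10.500000	0.0002287427
10.600000	0.0001777401
10.700000	0.0001377624
10.800000	0.0001065075
10.900000	0.0000821351
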