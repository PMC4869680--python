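time_s	value
0.000000	0.0000000000
0.100000	0.2197827657
0.200000	0.5805116338
0.300000	0.8574897147
0.400000	0.9930025956
0.500000	1.0000000000
0.600000	0.9145312570
0.700000	0.7741469950
0.800000	0.6095739735
0.900000	0.4427624790
1.000000	0.2876766046
1.100000	0.1520074079
1.200000	0.0389635966
1.300000	-0.0511999510
1.400000	-0.1200074626
1.500000	-0.1699222537
1.600000	-0.2037817590
1.700000	-0.2244409592
1.800000	-0.2345648100
1.900000	-0.2365221194
2.000000	-0.2323452282
2.100000	-0.2237300372
2.200000	-0.2120589244
2.300000	-0.1984350366
2.400000	-0.1837206778
2.500000	-0.1685754276
2.600000	-0.1534915703
2.700000	-0.1388256638
2.800000	-0.1248258533
2.900000	-0.1116549931
3.000000	-0.0994098823
3.100000	-0.0881370420
3.200000	-0.0778454926
3.300000	-0.0685169832
3.400000	-0.0601140880
3.500000	-0.0525865389
3.600000	-0.0458761173
3.700000	-0.0399203758
3.800000	-0.0346554223
3.900000	-0.0300179559
4.000000	-0.0259467132
4.100000	-0.0223834530
4.200000	-0.0192735859
4.300000	-0.0165665307
4.400000	-0.0142158677
4.500000	-0.0121793415
4.600000	-0.0104187559
4.700000	-0.0088997943
4.800000	-0.0075917920
4.900000	-0.0064674786
5.000000	-0.0055027071
5.100000	-0.0046761797
5.200000	-0.0039691782
5.300000	-0.0033653057
5.400000	-0.0028502412
5.500000	-0.0024115120
5.600000	-0.0020382831
5.700000	-0.0017211648
5.800000	-0.0014520381
5.900000	-0.0012238978
6.000000	-0.0010307114
6.100000	-0.0008672939
6.200000	-0.0007291967
6.300000	-0.0006126094
6.400000	-0.0005142732
6.500000	-0.0004314056
6.600000	-0.0003616337
6.700000	-0.0003029372
6.800000	-0.0002535980
6.900000	-0.0002121570
7.000000	-0.0001773760
7.100000	-0.0001482062
7.200000	-0.0001237597
7.300000	-0.0001032858
7.400000	-0.0000861505
7.500000	-0.0000718186
7.600000	-0.0000598390
7.700000	-0.0000498317
7.800000	-0.0000414770
7.900000	-0.0000345061
8.000000	-0.0000286929
8.100000	-0.0000238479
8.200000	-0.0000198119
8.300000	-0.0000164516
8.400000	-0.0000136553
8.500000	-0.0000113295
8.600000	-0.0000093959
8.700000	-0.0000077892
8.800000	-0.0000064547
8.900000	-0.0000053467
9.000000	-0.0000044272
9.100000	-0.0000036645
9.200000	-0.0000030321
9.300000	-0.0000025080
9.400000	-0.0000020737
9.500000	-0.0000017141
9.600000	-0.0000014163
9.700000	-0.0000011699
9.800000	-0.0000009661
9.900000	-0.0000007975
10.000000	-0.0000006581
10.100000	-0.0000005430
10.200000	-0.0000004478
10.300000	-0.0000003692
10.400000	-0.0000003043
10.500000	-0.0000002508
10.600000	-0.0000002066
10.700000	-0.0000001702
10.800000	-0.0000001401
10.900000	-0.0000001153
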