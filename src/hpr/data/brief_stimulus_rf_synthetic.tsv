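time_s	value
0.000000	0.0000000000
0.100000	0.0152911270
0.200000	0.0903493629
0.300000	0.2252135329
0.400000	0.3942814134
0.500000	0.5687638107
0.600000	0.7258908214
0.700000	0.8513483240
0.800000	0.9385960839
0.900000	0.9870335542
1.000000	1.0000000000
1.100000	0.9830456076
1.200000	0.9426163343
1.300000	0.8851500364
1.400000	0.8165194854
1.500000	0.7417402305
1.600000	0.6648652234
1.700000	0.5890010174
1.800000	0.5163954508
1.900000	0.4485607888
2.000000	0.3864079939
2.100000	0.3303768524
2.200000	0.2805532997
2.300000	0.2367698822
2.400000	0.1986882967
2.500000	0.1658647885
2.600000	0.1378001939
2.700000	0.1139768601
2.800000	0.0938847603
2.900000	0.0770389958
3.000000	0.0629906362
3.100000	0.0513325601
3.200000	0.0417016644
3.300000	0.0337785408
3.400000	0.0272854693
3.500000	0.0219833777
3.600000	0.0176682446
3.700000	0.0141672867
3.800000	0.0113351667
3.900000	0.0090503746
4.000000	0.0072118772
4.100000	0.0057360843
4.200000	0.0045541512
4.300000	0.0036096122
4.400000	0.0028563329
4.500000	0.0022567526
4.600000	0.0017803915
4.700000	0.0014025915
4.800000	0.0011034609
4.900000	0.0008669960
5.000000	0.0006803533
5.100000	0.0005332497
5.200000	0.0004174704
5.300000	0.0003264667
5.400000	0.0002550282
5.500000	0.0001990172
5.600000	0.0001551537
5.700000	0.0001208421
5.800000	0.0000940315
5.900000	0.0000731040
6.000000	0.0000567851
6.100000	0.0000440723
6.200000	0.0000341780
6.300000	0.0000264843
6.400000	0.0000205070
6.500000	0.0000158671
6.600000	0.0000122683
6.700000	0.0000094793
6.800000	0.0000073193
6.900000	0.0000056479
7.000000	0.0000043554
7.100000	0.0000033567
7.200000	0.0000025854
7.300000	0.0000019902
7.400000	0.0000015311
7.500000	0.0000011773
7.600000	0.0000009048
7.700000	0.0000006950
7.800000	0.0000005336
7.900000	0.0000004094
8.000000	0.0000003140
8.100000	0.0000002407
8.200000	0.0000001845
8.300000	0.0000001413
8.400000	0.0000001082
8.500000	0.0000000828
8.600000	0.0000000633
8.700000	0.0000000484
8.800000	0.0000000370
8.900000	0.0000000283
9.000000	0.0000000216
9.100000	0.0000000165
9.200000	0.0000000126
9.300000	0.0000000096
9.400000	0.0000000073
9.500000	0.0000000056
9.600000	0.0000000043
9.700000	0.0000000032
9.800000	0.0000000025
9.900000	0.0000000019
10.000000	0.0000000014
10.100000	0.0000000011
10.200000	0.0000000008
10.300000	0.0000000006
10.400000	0.0000000005
10.500000	0.0000000004
10.600000	0.0000000003
10.700000	0.0000000002
10.800000	0.0000000002
10.900000	0.0000000001
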