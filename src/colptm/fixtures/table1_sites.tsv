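# Site-specific collagen PTM catalog (zebrafish heart ECM), transcribed as printed.
# category: 3-HyP | HyK | G-HyK | GG-HyK; position is the full-length residue index.
# COL5A2a GG-HyK lists position 761 twice in the printed source; both entries are
# kept so printed-entry tallies reproduce the printed totals. COL2A1b is listed
# with no sites (category none).
chain	category	position
COL1A1a	3-HyP	176
COL1A1a	3-HyP	188
COL1A1a	3-HyP	317
COL1A1a	3-HyP	401
COL1A1a	3-HyP	443
COL1A1a	3-HyP	446
COL1A1a	3-HyP	551
COL1A1a	3-HyP	623
COL1A1a	3-HyP	707
COL1A1a	3-HyP	755
COL1A1a	3-HyP	800
COL1A1a	3-HyP	854
COL1A1a	3-HyP	869
COL1A1a	3-HyP	878
COL1A1a	3-HyP	881
COL1A1a	3-HyP	911
COL1A1a	3-HyP	980
COL1A1a	3-HyP	992
COL1A1a	3-HyP	1034
COL1A1a	3-HyP	1103
COL1A1a	3-HyP	1106
COL1A1a	3-HyP	1148
COL1A1a	3-HyP	1166
COL1A1a	3-HyP	1169
COL1A1a	HyK	261
COL1A1a	HyK	270
COL1A1a	HyK	336
COL1A1a	HyK	381
COL1A1a	HyK	414
COL1A1a	HyK	426
COL1A1a	HyK	432
COL1A1a	HyK	504
COL1A1a	HyK	522
COL1A1a	HyK	570
COL1A1a	HyK	596
COL1A1a	HyK	641
COL1A1a	HyK	693
COL1A1a	HyK	726
COL1A1a	HyK	735
COL1A1a	HyK	765
COL1A1a	HyK	810
COL1A1a	HyK	819
COL1A1a	HyK	846
COL1A1a	HyK	918
COL1A1a	HyK	1017
COL1A1a	HyK	1080
COL1A1a	HyK	1191
COL1A1a	G-HyK	261
COL1A1a	G-HyK	270
COL1A1a	G-HyK	432
COL1A1a	G-HyK	504
COL1A1a	G-HyK	570
COL1A1a	G-HyK	693
COL1A1a	G-HyK	819
COL1A1a	G-HyK	846
COL1A1a	G-HyK	1191
COL1A1a	GG-HyK	261
COL1A1a	GG-HyK	270
COL1A1a	GG-HyK	432
COL1A1a	GG-HyK	504
COL1A1a	GG-HyK	522
COL1A1a	GG-HyK	570
COL1A1a	GG-HyK	693
COL1A1a	GG-HyK	726
COL1A1a	GG-HyK	819
COL1A1a	GG-HyK	846
COL1A1a	GG-HyK	1017
COL1A1b	3-HyP	176
COL1A1b	3-HyP	191
COL1A1b	3-HyP	302
COL1A1b	3-HyP	320
COL1A1b	3-HyP	404
COL1A1b	3-HyP	470
COL1A1b	3-HyP	554
COL1A1b	3-HyP	758
COL1A1b	3-HyP	872
COL1A1b	3-HyP	881
COL1A1b	3-HyP	914
COL1A1b	3-HyP	938
COL1A1b	3-HyP	983
COL1A1b	3-HyP	1031
COL1A1b	3-HyP	1109
COL1A1b	3-HyP	1151
COL1A1b	3-HyP	1175
COL1A1b	HyK	215
COL1A1b	HyK	264
COL1A1b	HyK	273
COL1A1b	HyK	339
COL1A1b	HyK	384
COL1A1b	HyK	417
COL1A1b	HyK	429
COL1A1b	HyK	525
COL1A1b	HyK	573
COL1A1b	HyK	618
COL1A1b	HyK	696
COL1A1b	HyK	738
COL1A1b	HyK	746
COL1A1b	HyK	768
COL1A1b	HyK	813
COL1A1b	HyK	849
COL1A1b	HyK	900
COL1A1b	HyK	1020
COL1A1b	HyK	1193
COL1A1b	G-HyK	264
COL1A1b	G-HyK	273
COL1A1b	G-HyK	849
COL1A1b	G-HyK	1020
COL1A1b	GG-HyK	264
COL1A1b	GG-HyK	273
COL1A1b	GG-HyK	339
COL1A1b	GG-HyK	849
COL1A2	3-HyP	56
COL1A2	3-HyP	59
COL1A2	3-HyP	244
COL1A2	3-HyP	286
COL1A2	3-HyP	361
COL1A2	3-HyP	451
COL1A2	3-HyP	469
COL1A2	3-HyP	673
COL1A2	3-HyP	718
COL1A2	3-HyP	787
COL1A2	3-HyP	820
COL1A2	3-HyP	838
COL1A2	3-HyP	925
COL1A2	3-HyP	1066
COL1A2	3-HyP	1081
COL1A2	HyK	74
COL1A2	HyK	179
COL1A2	HyK	188
COL1A2	HyK	254
COL1A2	HyK	299
COL1A2	HyK	344
COL1A2	HyK	350
COL1A2	HyK	454
COL1A2	HyK	488
COL1A2	HyK	500
COL1A2	HyK	533
COL1A2	HyK	578
COL1A2	HyK	644
COL1A2	HyK	647
COL1A2	HyK	683
COL1A2	HyK	731
COL1A2	HyK	737
COL1A2	HyK	836
COL1A2	HyK	935
COL1A2	HyK	998
COL1A2	HyK	1004
COL1A2	G-HyK	74
COL1A2	G-HyK	188
COL1A2	G-HyK	254
COL1A2	G-HyK	344
COL1A2	G-HyK	350
COL1A2	G-HyK	644
COL1A2	GG-HyK	74
COL1A2	GG-HyK	167
COL1A2	GG-HyK	188
COL1A2	GG-HyK	254
COL1A2	GG-HyK	299
COL1A2	GG-HyK	578
COL1A2	GG-HyK	644
COL1A2	GG-HyK	647
COL1A2	GG-HyK	935
COL4A1	3-HyP	201
COL4A1	3-HyP	204
COL4A1	3-HyP	294
COL4A1	3-HyP	297
COL4A1	3-HyP	1338
COL4A1	GG-HyK	463
COL4A1	GG-HyK	466
COL4A1	GG-HyK	882
COL4A1	GG-HyK	909
COL4A1	GG-HyK	1149
COL4A1	GG-HyK	1179
COL4A1	GG-HyK	1182
COL5A1	3-HyP	686
COL5A1	3-HyP	746
COL5A1	3-HyP	824
COL5A1	3-HyP	1112
COL5A1	3-HyP	1115
COL5A1	3-HyP	1163
COL5A1	3-HyP	1166
COL5A1	3-HyP	1190
COL5A1	3-HyP	1193
COL5A1	3-HyP	1253
COL5A1	3-HyP	1421
COL5A1	3-HyP	1424
COL5A1	HyK	1134
COL5A1	HyK	1296
COL5A1	HyK	1329
COL5A1	HyK	1497
COL5A1	HyK	1578
COL5A1	HyK	1581
COL5A1	HyK	1592
COL5A1	HyK	1604
COL5A1	HyK	1644
COL5A1	G-HyK	1344
COL5A1	GG-HyK	623
COL5A1	GG-HyK	626
COL5A1	GG-HyK	753
COL5A1	GG-HyK	813
COL5A1	GG-HyK	945
COL5A1	GG-HyK	1104
COL5A1	GG-HyK	1209
COL5A1	GG-HyK	1245
COL5A1	GG-HyK	1290
COL5A1	GG-HyK	1338
COL5A1	GG-HyK	1383
COL5A1	GG-HyK	1455
COL5A1	GG-HyK	1482
COL5A1	GG-HyK	1578
COL5A1	GG-HyK	1581
COL5A2a	3-HyP	241
COL5A2a	3-HyP	277
COL5A2a	3-HyP	532
COL5A2a	3-HyP	661
COL5A2a	3-HyP	868
COL5A2a	3-HyP	901
COL5A2a	3-HyP	937
COL5A2a	3-HyP	967
COL5A2a	3-HyP	1105
COL5A2a	HyK	280
COL5A2a	HyK	329
COL5A2a	HyK	449
COL5A2a	HyK	482
COL5A2a	HyK	494
COL5A2a	HyK	709
COL5A2a	HyK	749
COL5A2a	HyK	803
COL5A2a	HyK	878
COL5A2a	HyK	986
COL5A2a	HyK	1036
COL5A2a	HyK	1078
COL5A2a	HyK	1124
COL5A2a	HyK	1135
COL5A2a	GG-HyK	329
COL5A2a	GG-HyK	338
COL5A2a	GG-HyK	500
COL5A2a	GG-HyK	557
COL5A2a	GG-HyK	572
COL5A2a	GG-HyK	761
COL5A2a	GG-HyK	761
COL5A2a	GG-HyK	794
COL5A2a	GG-HyK	638
COL5A2a	GG-HyK	803
COL5A2a	GG-HyK	887
COL6A1	3-HyP	574
COL6A1	3-HyP	577
COL6A1	HyK	482
COL6A1	HyK	538
COL6A1	GG-HyK	398
COL6A1	GG-HyK	488
COL6A1	GG-HyK	538
COL6A1	GG-HyK	560
COL6A1	GG-HyK	563
COL6A3	HyK	1796
COL6A3	HyK	1975
COL6A3	GG-HyK	1660
COL6A3	GG-HyK	1778
COL6A3	GG-HyK	1796
COL6A3	GG-HyK	1711
COL6A3	GG-HyK	1963
COL6A3	GG-HyK	1880
COL6A3	GG-HyK	1889
COL6A2	3-HyP	470
COL6A2	HyK	387
COL6A2	G-HyK	539
COL6A2	GG-HyK	339
COL6A2	GG-HyK	387
COL6A2	GG-HyK	426
COL6A2	GG-HyK	435
COL6A2	GG-HyK	438
COL6A2	GG-HyK	456
COL6A2	GG-HyK	459
COL6A2	GG-HyK	539
COL6A2	GG-HyK	545
COL11A1a	3-HyP	919
COL11A1a	HyK	1313
COL11A1a	G-HyK	1217
COL11A1a	G-HyK	1304
COL11A1a	GG-HyK	911
COL11A1a	GG-HyK	1148
COL11A1a	GG-HyK	1151
COL4A2	3-HyP	339
COL4A2	3-HyP	555
COL4A2	3-HyP	613
COL4A2	HyK	593
COL4A2	HyK	704
COL4A2	HyK	707
COL4A2	HyK	1620
COL4A2	HyK	1651
COL4A2	G-HyK	689
COL4A2	GG-HyK	54
COL4A2	GG-HyK	72
COL4A2	GG-HyK	318
COL4A2	GG-HyK	567
COL4A2	GG-HyK	582
COL4A2	GG-HyK	593
COL4A2	GG-HyK	662
COL4A2	GG-HyK	674
COL4A2	GG-HyK	689
COL4A2	GG-HyK	704
COL4A2	GG-HyK	707
COL4A2	GG-HyK	725
COL4A2	GG-HyK	948
COL4A2	GG-HyK	951
COL4A2	GG-HyK	969
COL4A2	GG-HyK	1045
COL4A2	GG-HyK	1048
COL4A2	GG-HyK	1076
COL4A2	GG-HyK	1235
COL4A2	GG-HyK	1247
COL4A2	GG-HyK	1283
COL4A2	GG-HyK	1292
COL4A2	GG-HyK	1331
COL4A2	GG-HyK	1346
COL4A5	3-HyP	93
COL4A5	HyK	127
COL4A5	HyK	214
COL4A5	G-HyK	225
COL4A5	GG-HyK	225
COL6A4a	G-HyK	1501
COL6A4a	GG-HyK	1490
COL6A4a	GG-HyK	1787
COL6A4a	GG-HyK	1796
COL6A4a	GG-HyK	2148
COL2A1a	HyK	612
COL2A1a	G-HyK	423
COL2A1a	GG-HyK	423
COL2A1a	GG-HyK	1178
COL2A1b	none	.
COL16A1	HyK	1008
COL16A1	HyK	1343
COL16A1	HyK	1495
COL16A1	HyK	1498
COL16A1	GG-HyK	644
COL16A1	GG-HyK	654
COL16A1	GG-HyK	1008
COL16A1	GG-HyK	1233
COL11A1b	GG-HyK	1191
COL11A1b	GG-HyK	1400
COL5A2b	3-HyP	838
COL5A2b	GG-HyK	731
COL11A2	3-HyP	1133
COL11A2	HyK	959
COL11A2	HyK	963
COL11A2	GG-HyK	1188
COL11A2	GG-HyK	1197
COL11A2	GG-HyK	1200
COL11A2	GG-HyK	1203
COL7A1	GG-HyK	1504
COL7A1	GG-HyK	2136
COL5A3b	3-HyP	437
COL5A3b	3-HyP	467
COL22A1	HyK	495
COL22A1	HyK	1128
COL22A1	G-HyK	788
COL22A1	G-HyK	1538
COL22A1	GG-HyK	498
COL22A1	GG-HyK	513
COL22A1	GG-HyK	785
COL17A1a	3-HyP	1156
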