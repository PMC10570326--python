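# Anomalous scattering coefficients for S (Z=16)
# Source: Cromer-Liberman relativistic calculation (as implemented in gemmi 0.7.4)
# Columns: energy_eV  f_prime_e  f_double_prime_e
# edge: K 2472.0
    1700.0      -1.3760       0.7289
    1732.8      -1.4154       0.7057
    1766.2      -1.4570       0.6832
    1800.2      -1.5013       0.6614
    1835.0      -1.5487       0.6402
    1870.3      -1.5994       0.6198
    1906.4      -1.6544       0.5999
    1943.2      -1.7141       0.5806
    1980.6      -1.7794       0.5619
    2018.8      -1.8518       0.5438
    2057.8      -1.9327       0.5263
    2097.4      -2.0237       0.5093
    2137.9      -2.1285       0.4928
    2179.1      -2.2506       0.4768
    2221.1      -2.3966       0.4613
    2263.9      -2.5763       0.4463
    2307.6      -2.8082       0.4318
    2352.1      -3.1276       0.4177
    2397.4      -3.6249       0.4040
    2443.7      -4.6899       0.3908
    2447.0      -4.8296       0.3899
    2464.0      -6.1377       0.3852
    2470.0      -7.7605       0.3836
    2471.5      -9.3958       0.3832
    2472.5      -9.4007       4.1081
    2474.0      -7.7508       4.1050
    2480.0      -6.0879       4.0926
    2490.8      -5.0471       4.0704
    2497.0      -4.6952       4.0576
    2538.8      -3.4532       3.9716
    2587.8      -2.7326       3.8708
    2637.7      -2.2229       3.7562
    2688.5      -1.8691       3.6434
    2740.4      -1.5880       3.5338
    2793.2      -1.3570       3.4278
    2847.1      -1.1619       3.3249
    2902.0      -0.9943       3.2253
    2957.9      -0.8487       3.1288
    3015.0      -0.7203       3.0353
    3073.1      -0.6061       2.9450
    3132.3      -0.5019       2.8571
    3192.7      -0.4105       2.7714
    3254.3      -0.3270       2.6878
    3317.1      -0.2528       2.6064
    3381.0      -0.1858       2.5273
    3446.2      -0.1250       2.4502
    3512.7      -0.0700       2.3752
    3580.4      -0.0198       2.3024
    3649.4       0.0255       2.2316
    3719.8       0.0667       2.1626
    3791.5       0.1040       2.0956
    3864.6       0.1379       2.0305
    3939.2       0.1687       1.9671
    4015.1       0.1965       1.9056
    4092.5       0.2216       1.8458
    4171.4       0.2443       1.7877
    4251.9       0.2647       1.7312
    4333.9       0.2845       1.6763
    4417.4       0.3009       1.6230
    4502.6       0.3154       1.5712
    4589.4       0.3283       1.5209
    4677.9       0.3397       1.4721
    4768.1       0.3497       1.4247
    4860.1       0.3583       1.3786
    4953.8       0.3700       1.3339
    5049.3       0.3761       1.2901
    5146.7       0.3811       1.2476
    5245.9       0.3851       1.2065
    5347.0       0.3883       1.1666
    5450.1       0.3906       1.1279
    5555.2       0.3921       1.0905
    5662.4       0.3929       1.0541
    5771.5       0.3931       1.0189
    5882.8       0.3927       0.9848
    5996.3       0.3917       0.9518
    6111.9       0.3902       0.9198
    6229.7       0.3883       0.8888
    6349.8       0.3859       0.8588
    6472.3       0.3832       0.8297
    6597.1       0.3800       0.8015
    6724.3       0.3766       0.7742
    6854.0       0.3729       0.7478
    6986.1       0.3689       0.7222
    7120.8       0.3646       0.6975
    7258.1       0.3601       0.6735
    7398.1       0.3555       0.6503
    7540.7       0.3506       0.6279
    7686.1       0.3456       0.6062
    7834.3       0.3405       0.5851
    7985.4       0.3352       0.5648
    8139.4       0.3299       0.5451
    8296.3       0.3244       0.5261
    8456.3       0.3189       0.5077
    8619.3       0.3133       0.4899
    8785.5       0.3077       0.4726
    8954.9       0.3020       0.4559
    9127.6       0.2962       0.4398
    9303.6       0.2904       0.4242
    9483.0       0.2847       0.4091
    9665.9       0.2789       0.3945
    9852.2       0.2731       0.3804
   10042.2       0.2673       0.3668
   10235.8       0.2616       0.3536
   10433.2       0.2558       0.3409
   10634.4       0.2501       0.3287
   10839.4       0.2462       0.3168
   11048.4       0.2405       0.3053
   11261.5       0.2349       0.2941
   11478.6       0.2293       0.2834
   11700.0       0.2237       0.2731
   11925.6       0.2182       0.2631
   12155.5       0.2128       0.2534
   12389.9       0.2075       0.2441
   12628.8       0.2022       0.2352
   12872.3       0.1970       0.2265
   13120.5       0.1919       0.2182
   13373.5       0.1868       0.2101
   13631.4       0.1819       0.2024
   13894.2       0.1770       0.1949
   14162.1       0.1721       0.1877
   14435.2       0.1674       0.1807
   14713.6       0.1628       0.1740
   14997.3       0.1582       0.1676
   15286.4       0.1537       0.1613
   15581.2       0.1493       0.1553
   15881.6       0.1450       0.1495
   16187.9       0.1408       0.1439
   16500.0       0.1366       0.1385
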