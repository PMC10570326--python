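# Anomalous scattering coefficients for Se (Z=34)
# Source: Cromer-Liberman relativistic calculation (as implemented in gemmi 0.7.4)
# Columns: energy_eV  f_prime_e  f_double_prime_e
# edge: K 12657.8
    1700.0      -7.5613      14.5128
    1732.8      -6.6534      14.1031
    1766.2      -5.9544      13.7160
    1800.2      -5.3419      13.3397
    1835.0      -4.8070      12.9710
    1870.3      -4.3565      12.6136
    1906.4      -3.9343      12.2670
    1943.2      -3.5639      11.9296
    1980.6      -3.2209      11.6015
    2018.8      -2.9088      11.2804
    2057.8      -2.6241      10.9663
    2097.4      -2.3653      10.6607
    2137.9      -2.1277      10.3614
    2179.1      -1.9080      10.0693
    2221.1      -1.7093       9.7841
    2263.9      -1.5273       9.5059
    2307.6      -1.3602       9.2340
    2352.1      -1.2073       8.9691
    2397.4      -1.0673       8.7110
    2443.7      -0.9387       8.4587
    2490.8      -0.8214       8.2132
    2538.8      -0.7141       7.9739
    2587.8      -0.6161       7.7403
    2637.7      -0.5269       7.5129
    2688.5      -0.4460       7.2915
    2740.4      -0.3723       7.0754
    2793.2      -0.3059       6.8653
    2847.1      -0.2459       6.6603
    2902.0      -0.1914       6.4608
    2957.9      -0.1436       6.2668
    3015.0      -0.0996       6.0772
    3073.1      -0.0511       5.8919
    3132.3      -0.0184       5.7118
    3192.7       0.0134       5.5367
    3254.3       0.0364       5.3664
    3317.1       0.0601       5.2010
    3381.0       0.0753       5.0401
    3446.2       0.0872       4.8838
    3512.7       0.0960       4.7320
    3580.4       0.1020       4.5848
    3649.4       0.1053       4.4419
    3719.8       0.1061       4.3030
    3791.5       0.1047       4.1684
    3864.6       0.1011       4.0377
    3939.2       0.0956       3.9107
    4015.1       0.0883       3.7877
    4092.5       0.0793       3.6683
    4171.4       0.0687       3.5524
    4251.9       0.0566       3.4399
    4333.9       0.0432       3.3308
    4417.4       0.0285       3.2251
    4502.6       0.0127       3.1225
    4589.4      -0.0042       3.0230
    4677.9      -0.0221       2.9265
    4768.1      -0.0410       2.8329
    4860.1      -0.0607       2.7421
    4953.8      -0.0812       2.6541
    5049.3      -0.1025       2.5688
    5146.7      -0.1244       2.4861
    5245.9      -0.1471       2.4060
    5347.0      -0.1703       2.3283
    5450.1      -0.1941       2.2530
    5555.2      -0.2185       2.1799
    5662.4      -0.2434       2.1091
    5771.5      -0.2687       2.0406
    5882.8      -0.2946       1.9741
    5996.3      -0.3210       1.9097
    6111.9      -0.3477       1.8473
    6229.7      -0.3728       1.7868
    6349.8      -0.4007       1.7282
    6472.3      -0.4278       1.6713
    6597.1      -0.4566       1.6162
    6724.3      -0.4859       1.5628
    6854.0      -0.5157       1.5112
    6986.1      -0.5459       1.4612
    7120.8      -0.5766       1.4128
    7258.1      -0.6068       1.3659
    7398.1      -0.6388       1.3205
    7540.7      -0.6714       1.2766
    7686.1      -0.7048       1.2340
    7834.3      -0.7389       1.1929
    7985.4      -0.7738       1.1531
    8139.4      -0.8097       1.1145
    8296.3      -0.8467       1.0773
    8456.3      -0.8848       1.0412
    8619.3      -0.9243       1.0063
    8785.5      -0.9652       0.9725
    8954.9      -1.0078       0.9397
    9127.6      -1.0521       0.9076
    9303.6      -1.0988       0.8765
    9483.0      -1.1482       0.8465
    9665.9      -1.2009       0.8175
    9852.2      -1.2572       0.7896
   10042.2      -1.3180       0.7625
   10235.8      -1.3840       0.7364
   10433.2      -1.4565       0.7111
   10634.4      -1.5369       0.6867
   10839.4      -1.6273       0.6632
   11048.4      -1.7308       0.6404
   11261.5      -1.8516       0.6184
   11478.6      -1.9964       0.5971
   11700.0      -2.1768       0.5766
   11925.6      -2.4140       0.5568
   12155.5      -2.7554       0.5376
   12389.9      -3.3467       0.5191
   12628.8      -5.5937       0.5012
   12632.8      -5.7486       0.5009
   12649.8      -6.9460       0.4997
   12655.8      -8.4125       0.4993
   12657.3      -9.8829       0.4992
   12658.3      -9.8993       3.8438
   12659.8      -8.4217       3.8428
   12665.8      -6.9393       3.8389
   12682.8      -5.7119       3.8278
   12872.3      -3.3347       3.7091
   13120.5      -2.4585       3.5656
   13373.5      -2.0201       3.4416
   13631.4      -1.6722       3.3390
   13894.2      -1.4043       3.2391
   14162.1      -1.1878       3.1418
   14435.2      -1.0074       3.0470
   14713.6      -0.8541       2.9548
   14997.3      -0.7217       2.8650
   15286.4      -0.6063       2.7777
   15581.2      -0.5047       2.6927
   15881.6      -0.4148       2.6100
   16187.9      -0.3348       2.5295
   16500.0      -0.2599       2.4511
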