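# Anomalous scattering coefficients for Zn (Z=30)
# Source: Cromer-Liberman relativistic calculation (as implemented in gemmi 0.7.4)
# Columns: energy_eV  f_prime_e  f_double_prime_e
# edge: K 9658.6
    1700.0      -1.4086       9.2140
    1732.8      -1.2626       8.9555
    1766.2      -1.1284       8.7035
    1800.2      -1.0051       8.4578
    1835.0      -0.8913       8.2171
    1870.3      -0.7874       7.9835
    1906.4      -0.6917       7.7548
    1943.2      -0.6042       7.5317
    1980.6      -0.5244       7.3149
    2018.8      -0.4515       7.1030
    2057.8      -0.3756       6.8957
    2097.4      -0.3112       6.6938
    2137.9      -0.2581       6.4962
    2179.1      -0.2105       6.3042
    2221.1      -0.1680       6.1173
    2263.9      -0.1303       5.9355
    2307.6      -0.0969       5.7583
    2352.1      -0.0677       5.5860
    2397.4      -0.0404       5.4185
    2443.7      -0.0189       5.2551
    2490.8      -0.0009       5.0964
    2538.8       0.0139       4.9422
    2587.8       0.0260       4.7920
    2637.7       0.0350       4.6461
    2688.5       0.0414       4.5045
    2740.4       0.0454       4.3665
    2793.2       0.0470       4.2327
    2847.1       0.0466       4.1024
    2902.0       0.0441       3.9759
    2957.9       0.0398       3.8532
    3015.0       0.0339       3.7334
    3073.1       0.0263       3.6166
    3132.3       0.0172       3.5033
    3192.7       0.0065       3.3933
    3254.3      -0.0056       3.2864
    3317.1      -0.0190       3.1828
    3381.0      -0.0336       3.0823
    3446.2      -0.0493       2.9848
    3512.7      -0.0660       2.8902
    3580.4      -0.0837       2.7985
    3649.4      -0.1023       2.7096
    3719.8      -0.1207       2.6232
    3791.5      -0.1410       2.5396
    3864.6      -0.1619       2.4584
    3939.2      -0.1836       2.3796
    4015.1      -0.2058       2.3034
    4092.5      -0.2286       2.2294
    4171.4      -0.2520       2.1577
    4251.9      -0.2759       2.0882
    4333.9      -0.3003       2.0208
    4417.4      -0.3254       1.9555
    4502.6      -0.3466       1.8920
    4589.4      -0.3705       1.8303
    4677.9      -0.3971       1.7706
    4768.1      -0.4242       1.7128
    4860.1      -0.4517       1.6567
    4953.8      -0.4796       1.6025
    5049.3      -0.5080       1.5499
    5146.7      -0.5368       1.4990
    5245.9      -0.5633       1.4497
    5347.0      -0.5932       1.4018
    5450.1      -0.6237       1.3555
    5555.2      -0.6548       1.3107
    5662.4      -0.6865       1.2673
    5771.5      -0.7188       1.2253
    5882.8      -0.7519       1.1847
    5996.3      -0.7858       1.1453
    6111.9      -0.8206       1.1072
    6229.7      -0.8564       1.0704
    6349.8      -0.8933       1.0348
    6472.3      -0.9314       1.0003
    6597.1      -0.9710       0.9669
    6724.3      -1.0121       0.9346
    6854.0      -1.0551       0.9033
    6986.1      -1.1002       0.8731
    7120.8      -1.1477       0.8439
    7258.1      -1.1980       0.8156
    7398.1      -1.2516       0.7882
    7540.7      -1.3090       0.7617
    7686.1      -1.3711       0.7361
    7834.3      -1.4387       0.7113
    7985.4      -1.5131       0.6873
    8139.4      -1.5960       0.6641
    8296.3      -1.6895       0.6417
    8456.3      -1.7969       0.6200
    8619.3      -1.9229       0.5990
    8785.5      -2.0751       0.5787
    8954.9      -2.2662       0.5590
    9127.6      -2.5207       0.5397
    9303.6      -2.8948       0.5211
    9483.0      -3.5758       0.5031
    9633.6      -5.5790       0.4888
    9650.6      -6.7703       0.4872
    9656.6      -8.1531       0.4866
    9658.1      -9.2942       0.4865
    9659.1     -10.8152       3.8969
    9660.6      -8.4880       3.8956
    9665.9      -6.9442       3.8912
    9666.6      -6.8399       3.8906
    9683.6      -5.5570       3.8765
    9852.2      -3.2278       3.7427
   10042.2      -2.4311       3.6037
   10235.8      -2.0042       3.4856
   10433.2      -1.6638       3.3824
   10634.4      -1.3985       3.2818
   10839.4      -1.1828       3.1839
   11048.4      -1.0023       3.0885
   11261.5      -0.8481       2.9955
   11478.6      -0.7147       2.9051
   11700.0      -0.5981       2.8170
   11925.6      -0.4953       2.7312
   12155.5      -0.4043       2.6477
   12389.9      -0.3237       2.5665
   12628.8      -0.2418       2.4871
   12872.3      -0.1793       2.4094
   13120.5      -0.1214       2.3338
   13373.5      -0.0692       2.2604
   13631.4      -0.0223       2.1892
   13894.2       0.0200       2.1199
   14162.1       0.0581       2.0527
   14435.2       0.0924       1.9874
   14713.6       0.1232       1.9240
   14997.3       0.1508       1.8625
   15286.4       0.1756       1.8027
   15581.2       0.1978       1.7447
   15881.6       0.2176       1.6885
   16187.9       0.2352       1.6338
   16500.0       0.2507       1.5808
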