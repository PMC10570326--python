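# Anomalous scattering coefficients for P (Z=15)
# Source: Cromer-Liberman relativistic calculation (as implemented in gemmi 0.7.4)
# Columns: energy_eV  f_prime_e  f_double_prime_e
# edge: K 2145.5
    1700.0      -1.7998       0.5497
    1732.8      -1.8682       0.5321
    1766.2      -1.9441       0.5150
    1800.2      -2.0292       0.4985
    1835.0      -2.1265       0.4824
    1870.3      -2.2385       0.4669
    1906.4      -2.3710       0.4518
    1943.2      -2.5313       0.4372
    1980.6      -2.7318       0.4231
    2018.8      -2.9970       0.4094
    2057.8      -3.3790       0.3961
    2097.4      -4.0273       0.3832
    2120.5      -4.7595       0.3760
    2137.5      -6.0738       0.3708
    2137.9      -6.1337       0.3707
    2143.5      -7.7051       0.3690
    2145.0      -9.3495       0.3686
    2146.0      -9.3532       4.1142
    2147.5      -7.6941       4.1112
    2153.5      -6.0216       4.0993
    2170.5      -4.6194       4.0652
    2179.1      -4.2477       4.0478
    2221.1      -3.2010       3.9618
    2263.9      -2.5407       3.8644
    2307.6      -2.1163       3.7484
    2352.1      -1.7907       3.6359
    2397.4      -1.5280       3.5270
    2443.7      -1.3085       3.4210
    2490.8      -1.1215       3.3183
    2538.8      -0.9604       3.2187
    2587.8      -0.8194       3.1218
    2637.7      -0.6951       3.0280
    2688.5      -0.5848       2.9370
    2740.4      -0.4861       2.8486
    2793.2      -0.4005       2.7630
    2847.1      -0.3200       2.6801
    2902.0      -0.2472       2.5995
    2957.9      -0.1813       2.5211
    3015.0      -0.1213       2.4445
    3073.1      -0.0667       2.3699
    3132.3      -0.0173       2.2974
    3192.7       0.0276       2.2268
    3254.3       0.0684       2.1581
    3317.1       0.1055       2.0914
    3381.0       0.1390       2.0265
    3446.2       0.1695       1.9635
    3512.7       0.1970       1.9021
    3580.4       0.2239       1.8426
    3649.4       0.2463       1.7846
    3719.8       0.2665       1.7283
    3791.5       0.2846       1.6736
    3864.6       0.3009       1.6205
    3939.2       0.3154       1.5689
    4015.1       0.3282       1.5188
    4092.5       0.3395       1.4702
    4171.4       0.3495       1.4229
    4251.9       0.3581       1.3770
    4333.9       0.3706       1.3322
    4417.4       0.3766       1.2885
    4502.6       0.3817       1.2462
    4589.4       0.3857       1.2051
    4677.9       0.3888       1.1653
    4768.1       0.3912       1.1267
    4860.1       0.3927       1.0893
    4953.8       0.3936       1.0530
    5049.3       0.3938       1.0179
    5146.7       0.3934       0.9839
    5245.9       0.3924       0.9509
    5347.0       0.3910       0.9190
    5450.1       0.3890       0.8880
    5555.2       0.3867       0.8581
    5662.4       0.3840       0.8290
    5771.5       0.3809       0.8009
    5882.8       0.3775       0.7737
    5996.3       0.3738       0.7473
    6111.9       0.3698       0.7218
    6229.7       0.3656       0.6971
    6349.8       0.3612       0.6732
    6472.3       0.3566       0.6500
    6597.1       0.3518       0.6276
    6724.3       0.3469       0.6059
    6854.0       0.3418       0.5849
    6986.1       0.3366       0.5646
    7120.8       0.3312       0.5450
    7258.1       0.3258       0.5260
    7398.1       0.3203       0.5076
    7540.7       0.3148       0.4898
    7686.1       0.3092       0.4726
    7834.3       0.3035       0.4560
    7985.4       0.2979       0.4399
    8139.4       0.2922       0.4243
    8296.3       0.2865       0.4093
    8456.3       0.2808       0.3948
    8619.3       0.2751       0.3807
    8785.5       0.2694       0.3671
    8954.9       0.2637       0.3540
    9127.6       0.2580       0.3413
    9303.6       0.2545       0.3290
    9483.0       0.2488       0.3170
    9665.9       0.2431       0.3055
    9852.2       0.2374       0.2943
   10042.2       0.2318       0.2836
   10235.8       0.2263       0.2732
   10433.2       0.2209       0.2632
   10634.4       0.2154       0.2536
   10839.4       0.2101       0.2443
   11048.4       0.2049       0.2353
   11261.5       0.1997       0.2266
   11478.6       0.1945       0.2183
   11700.0       0.1895       0.2102
   11925.6       0.1845       0.2024
   12155.5       0.1796       0.1949
   12389.9       0.1748       0.1877
   12628.8       0.1701       0.1807
   12872.3       0.1655       0.1740
   13120.5       0.1609       0.1676
   13373.5       0.1564       0.1613
   13631.4       0.1520       0.1553
   13894.2       0.1477       0.1495
   14162.1       0.1435       0.1439
   14435.2       0.1394       0.1385
   14713.6       0.1353       0.1333
   14997.3       0.1313       0.1283
   15286.4       0.1274       0.1235
   15581.2       0.1236       0.1189
   15881.6       0.1199       0.1144
   16187.9       0.1162       0.1101
   16500.0       0.1126       0.1059
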