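# Anomalous scattering coefficients for Cl (Z=17)
# Source: Cromer-Liberman relativistic calculation (as implemented in gemmi 0.7.4)
# Columns: energy_eV  f_prime_e  f_double_prime_e
# edge: K 2822.4
    1700.0      -1.0852       0.9471
    1732.8      -1.1149       0.9171
    1766.2      -1.1457       0.8881
    1800.2      -1.1776       0.8599
    1835.0      -1.2109       0.8325
    1870.3      -1.2454       0.8060
    1906.4      -1.2816       0.7803
    1943.2      -1.3196       0.7553
    1980.6      -1.3595       0.7312
    2018.8      -1.4018       0.7078
    2057.8      -1.4467       0.6850
    2097.4      -1.4945       0.6630
    2137.9      -1.5459       0.6417
    2179.1      -1.6012       0.6210
    2221.1      -1.6613       0.6009
    2263.9      -1.7271       0.5815
    2307.6      -1.7999       0.5626
    2352.1      -1.8810       0.5444
    2397.4      -1.9724       0.5267
    2443.7      -2.0776       0.5095
    2490.8      -2.2001       0.4929
    2538.8      -2.3465       0.4768
    2587.8      -2.5275       0.4612
    2637.7      -2.7608       0.4461
    2688.5      -3.0835       0.4314
    2740.4      -3.5931       0.4172
    2793.2      -4.7202       0.4035
    2797.4      -4.8944       0.4025
    2814.4      -6.1953       0.3982
    2820.4      -7.8074       0.3967
    2821.9      -9.4309       0.3963
    2822.9      -9.4377       4.0946
    2824.4      -7.7997       4.0918
    2830.4      -6.1497       4.0806
    2847.1      -4.7834       4.0492
    2847.4      -4.7686       4.0487
    2902.0      -3.3111       3.9431
    2957.9      -2.6137       3.8312
    3015.0      -2.1491       3.7157
    3073.1      -1.8082       3.6062
    3132.3      -1.5345       3.4996
    3192.7      -1.3085       3.3957
    3254.3      -1.1171       3.2946
    3317.1      -0.9522       3.1961
    3381.0      -0.8088       3.1005
    3446.2      -0.6824       3.0073
    3512.7      -0.5704       2.9167
    3580.4      -0.4706       2.8286
    3649.4      -0.3812       2.7429
    3719.8      -0.3027       2.6597
    3791.5      -0.2285       2.5789
    3864.6      -0.1631       2.5003
    3939.2      -0.1039       2.4237
    4015.1      -0.0503       2.3493
    4092.5      -0.0018       2.2770
    4171.4       0.0423       2.2067
    4251.9       0.0823       2.1382
    4333.9       0.1186       2.0717
    4417.4       0.1514       2.0071
    4502.6       0.1811       1.9442
    4589.4       0.2080       1.8832
    4677.9       0.2322       1.8238
    4768.1       0.2541       1.7662
    4860.1       0.2737       1.7101
    4953.8       0.2913       1.6557
    5049.3       0.3070       1.6029
    5146.7       0.3220       1.5515
    5245.9       0.3343       1.5017
    5347.0       0.3450       1.4533
    5450.1       0.3544       1.4063
    5555.2       0.3625       1.3607
    5662.4       0.3726       1.3163
    5771.5       0.3782       1.2730
    5882.8       0.3828       1.2311
    5996.3       0.3864       1.1904
    6111.9       0.3892       1.1509
    6229.7       0.3911       1.1127
    6349.8       0.3923       1.0757
    6472.3       0.3928       1.0398
    6597.1       0.3927       1.0050
    6724.3       0.3920       0.9713
    6854.0       0.3907       0.9387
    6986.1       0.3890       0.9070
    7120.8       0.3868       0.8764
    7258.1       0.3842       0.8467
    7398.1       0.3812       0.8180
    7540.7       0.3779       0.7902
    7686.1       0.3743       0.7632
    7834.3       0.3704       0.7371
    7985.4       0.3663       0.7119
    8139.4       0.3618       0.6874
    8296.3       0.3572       0.6637
    8456.3       0.3524       0.6408
    8619.3       0.3475       0.6187
    8785.5       0.3423       0.5972
    8954.9       0.3371       0.5764
    9127.6       0.3317       0.5562
    9303.6       0.3262       0.5367
    9483.0       0.3207       0.5178
    9665.9       0.3150       0.4996
    9852.2       0.3093       0.4820
   10042.2       0.3035       0.4649
   10235.8       0.2977       0.4485
   10433.2       0.2919       0.4326
   10634.4       0.2861       0.4172
   10839.4       0.2802       0.4023
   11048.4       0.2744       0.3880
   11261.5       0.2685       0.3741
   11478.6       0.2627       0.3607
   11700.0       0.2569       0.3478
   11925.6       0.2512       0.3353
   12155.5       0.2455       0.3233
   12389.9       0.2415       0.3115
   12628.8       0.2358       0.3002
   12872.3       0.2301       0.2893
   13120.5       0.2245       0.2787
   13373.5       0.2190       0.2685
   13631.4       0.2135       0.2587
   13894.2       0.2081       0.2492
   14162.1       0.2027       0.2401
   14435.2       0.1974       0.2312
   14713.6       0.1922       0.2227
   14997.3       0.1871       0.2145
   15286.4       0.1821       0.2066
   15581.2       0.1771       0.1990
   15881.6       0.1722       0.1916
   16187.9       0.1674       0.1845
   16500.0       0.1627       0.1777
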