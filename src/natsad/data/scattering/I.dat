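# Anomalous scattering coefficients for I (Z=53)
# Source: Cromer-Liberman relativistic calculation (as implemented in gemmi 0.7.4)
# Columns: energy_eV  f_prime_e  f_double_prime_e
# edge: L3 4557.1
# edge: L2 4852.1
# edge: L1 5188.1
    1700.0      -5.4404      14.4525
    1732.8      -5.3374      14.0850
    1766.2      -5.2438      13.7256
    1800.2      -5.1592      13.3743
    1835.0      -5.0828      13.0291
    1870.3      -5.0147      12.6930
    1906.4      -4.9543      12.3631
    1943.2      -4.9013      12.0404
    1980.6      -4.8556      11.7258
    2018.8      -4.8166      11.4174
    2057.8      -4.7843      11.1155
    2097.4      -4.7584      10.8216
    2137.9      -4.7387      10.5333
    2179.1      -4.7219      10.2518
    2221.1      -4.7142       9.9767
    2263.9      -4.7122       9.7081
    2307.6      -4.7153       9.4453
    2352.1      -4.7243       9.1889
    2397.4      -4.7385       8.9388
    2443.7      -4.7580       8.6940
    2490.8      -4.7758       8.4555
    2538.8      -4.8009       8.2224
    2587.8      -4.8377       7.9945
    2637.7      -4.8794       7.7724
    2688.5      -4.9261       7.5562
    2740.4      -4.9782       7.3450
    2793.2      -5.0354       7.1394
    2847.1      -5.0981       6.9387
    2902.0      -5.1664       6.7432
    2957.9      -5.2405       6.5529
    3015.0      -5.3205       6.3665
    3073.1      -5.4061       6.1836
    3132.3      -5.4993       6.0057
    3192.7      -5.6005       5.8325
    3254.3      -5.7103       5.6639
    3317.1      -5.8292       5.4998
    3381.0      -5.9579       5.3405
    3446.2      -6.0979       5.1854
    3512.7      -6.2366       5.0343
    3580.4      -6.4038       4.8869
    3649.4      -6.5875       4.7436
    3719.8      -6.7906       4.6042
    3791.5      -7.0070       4.4682
    3864.6      -7.2612       4.3361
    3939.2      -7.5504       4.2075
    4015.1      -7.8831       4.0827
    4092.5      -8.2741       3.9615
    4171.4      -8.7455       3.8436
    4251.9      -9.3361       3.7290
    4333.9     -10.1200       3.6177
    4417.4     -11.2801       3.5096
    4502.6     -13.5692       3.4046
    4532.1     -15.4435       3.3693
    4549.1     -18.1785       3.3493
    4555.1     -21.5104       3.3423
    4556.6     -24.8471       3.3405
    4557.6     -24.8802      10.9314
    4559.1     -21.5232      10.9230
    4565.1     -18.1582      10.8900
    4582.1     -15.3969      10.7974
    4589.4     -14.7826      10.7582
    4677.9     -11.8733      10.3073
    4768.1     -11.2936       9.8903
    4827.1     -12.2786       9.6794
    4844.1     -13.4765       9.6235
    4850.1     -15.0777       9.6039
    4851.6     -16.7223       9.5990
    4852.6     -16.7299      13.3682
    4854.1     -15.0486      13.3604
    4860.1     -13.3239      13.3292
    4877.1     -11.8063      13.2417
    4953.8      -9.6246      12.8602
    5049.3      -8.5079      12.4141
    5146.7      -8.3122      12.0119
    5163.1      -8.4632      11.9491
    5180.1      -8.9824      11.8846
    5186.1      -9.7375      11.8619
    5187.6     -10.5298      11.8562
    5188.6     -10.5254      13.6788
    5190.1      -9.7073      13.6729
    5196.1      -8.8532      13.6490
    5213.1      -8.0593      13.5817
    5245.9      -7.3338      13.4532
    5347.0      -6.1097      13.0688
    5450.1      -5.2834      12.6937
    5555.2      -4.6288      12.3277
    5662.4      -4.0816      11.9707
    5771.5      -3.6129      11.6233
    5882.8      -3.2040      11.2844
    5996.3      -2.8376      10.9534
    6111.9      -2.5185      10.6308
    6229.7      -2.2340      10.3168
    6349.8      -1.9751      10.0107
    6472.3      -1.7463       9.7122
    6597.1      -1.5405       9.4219
    6724.3      -1.3550       9.1395
    6854.0      -1.1861       8.8644
    6986.1      -1.0353       8.5970
    7120.8      -0.8992       8.3369
    7258.1      -0.7765       8.0840
    7398.1      -0.6658       7.8380
    7540.7      -0.5663       7.5991
    7686.1      -0.4769       7.3667
    7834.3      -0.3968       7.1409
    7985.4      -0.3251       6.9213
    8139.4      -0.2614       6.7080
    8296.3      -0.2048       6.5008
    8456.3      -0.1549       6.2995
    8619.3      -0.1111       6.1039
    8785.5      -0.0731       5.9139
    8954.9      -0.0405       5.7291
    9127.6      -0.0081       5.5493
    9303.6       0.0144       5.3743
    9483.0       0.0326       5.2046
    9665.9       0.0470       5.0399
    9852.2       0.0621       4.8800
   10042.2       0.0694       4.7247
   10235.8       0.0737       4.5743
   10433.2       0.0784       4.4282
   10634.4       0.0771       4.2864
   10839.4       0.0733       4.1490
   11048.4       0.0673       4.0158
   11261.5       0.0593       3.8867
   11478.6       0.0493       3.7616
   11700.0       0.0382       3.6404
   11925.6       0.0253       3.5229
   12155.5       0.0104       3.4090
   12389.9      -0.0059       3.2987
   12628.8      -0.0234       3.1918
   12872.3      -0.0421       3.0883
   13120.5      -0.0619       2.9880
   13373.5      -0.0827       2.8908
   13631.4      -0.1045       2.7966
   13894.2      -0.1270       2.7054
   14162.1      -0.1504       2.6171
   14435.2      -0.1745       2.5316
   14713.6      -0.1993       2.4487
   14997.3      -0.2247       2.3685
   15286.4      -0.2508       2.2908
   15581.2      -0.2774       2.2155
   15881.6      -0.3045       2.1426
   16187.9      -0.3322       2.0721
   16500.0      -0.3592       2.0037
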