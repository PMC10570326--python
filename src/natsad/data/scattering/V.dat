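# Anomalous scattering coefficients for V (Z=23)
# Source: Cromer-Liberman relativistic calculation (as implemented in gemmi 0.7.4)
# Columns: energy_eV  f_prime_e  f_double_prime_e
# edge: K 5465.1
    1700.0      -0.1798       3.3409
    1732.8      -0.1865       3.2399
    1766.2      -0.1946       3.1418
    1800.2      -0.2038       3.0466
    1835.0      -0.2142       2.9536
    1870.3      -0.2256       2.8636
    1906.4      -0.2381       2.7759
    1943.2      -0.2514       2.6907
    1980.6      -0.2656       2.6081
    2018.8      -0.2807       2.5277
    2057.8      -0.2926       2.4494
    2097.4      -0.3073       2.3734
    2137.9      -0.3251       2.2994
    2179.1      -0.3435       2.2276
    2221.1      -0.3625       2.1579
    2263.9      -0.3821       2.0903
    2307.6      -0.4022       2.0246
    2352.1      -0.4229       1.9609
    2397.4      -0.4440       1.8992
    2443.7      -0.4658       1.8391
    2490.8      -0.4879       1.7809
    2538.8      -0.5090       1.7244
    2587.8      -0.5323       1.6695
    2637.7      -0.5561       1.6163
    2688.5      -0.5802       1.5648
    2740.4      -0.6049       1.5148
    2793.2      -0.6301       1.4663
    2847.1      -0.6557       1.4193
    2902.0      -0.6818       1.3737
    2957.9      -0.7085       1.3296
    3015.0      -0.7356       1.2866
    3073.1      -0.7630       1.2446
    3132.3      -0.7911       1.2040
    3192.7      -0.8201       1.1646
    3254.3      -0.8499       1.1264
    3317.1      -0.8805       1.0895
    3381.0      -0.9121       1.0538
    3446.2      -0.9446       1.0191
    3512.7      -0.9784       0.9856
    3580.4      -1.0133       0.9532
    3649.4      -1.0495       0.9218
    3719.8      -1.0874       0.8914
    3791.5      -1.1269       0.8619
    3864.6      -1.1683       0.8334
    3939.2      -1.2120       0.8058
    4015.1      -1.2582       0.7792
    4092.5      -1.3073       0.7533
    4171.4      -1.3598       0.7283
    4251.9      -1.4163       0.7041
    4333.9      -1.4775       0.6807
    4417.4      -1.5444       0.6580
    4502.6      -1.6182       0.6361
    4589.4      -1.7005       0.6149
    4677.9      -1.7935       0.5943
    4768.1      -1.9004       0.5744
    4860.1      -2.0259       0.5552
    4953.8      -2.1768       0.5366
    5049.3      -2.3655       0.5186
    5146.7      -2.6143       0.5011
    5245.9      -2.9724       0.4843
    5347.0      -3.5899       0.4680
    5440.1      -5.2375       0.4537
    5450.1      -5.7982       0.4522
    5457.1      -6.4949       0.4512
    5463.1      -8.0447       0.4503
    5464.6      -9.6022       0.4501
    5465.6      -9.6144       3.9957
    5467.1      -8.0457       3.9935
    5473.1      -6.4683       3.9849
    5490.1      -5.1550       3.9608
    5555.2      -3.6398       3.8711
    5662.4      -2.6894       3.7326
    5771.5      -2.1966       3.6093
    5882.8      -1.8194       3.5033
    5996.3      -1.5285       3.4001
    6111.9      -1.2933       3.2995
    6229.7      -1.0971       3.2015
    6349.8      -0.9298       3.1060
    6472.3      -0.7851       3.0129
    6597.1      -0.6586       2.9223
    6724.3      -0.5470       2.8340
    6854.0      -0.4480       2.7480
    6986.1      -0.3597       2.6644
    7120.8      -0.2789       2.5829
    7258.1      -0.2081       2.5033
    7398.1      -0.1443       2.4259
    7540.7      -0.0869       2.3507
    7686.1      -0.0351       2.2775
    7834.3       0.0118       2.2064
    7985.4       0.0541       2.1373
    8139.4       0.0923       2.0701
    8296.3       0.1268       2.0048
    8456.3       0.1579       1.9413
    8619.3       0.1859       1.8797
    8785.5       0.2112       1.8198
    8954.9       0.2338       1.7616
    9127.6       0.2539       1.7049
    9303.6       0.2718       1.6499
    9483.0       0.2878       1.5965
    9665.9       0.3025       1.5447
    9852.2       0.3153       1.4945
   10042.2       0.3260       1.4457
   10235.8       0.3353       1.3985
   10433.2       0.3433       1.3526
   10634.4       0.3501       1.3081
   10839.4       0.3557       1.2650
   11048.4       0.3641       1.2230
   11261.5       0.3675       1.1821
   11478.6       0.3700       1.1425
   11700.0       0.3717       1.1041
   11925.6       0.3738       1.0670
   12155.5       0.3740       1.0310
   12389.9       0.3735       0.9961
   12628.8       0.3725       0.9624
   12872.3       0.3709       0.9297
   13120.5       0.3688       0.8981
   13373.5       0.3663       0.8675
   13631.4       0.3634       0.8378
   13894.2       0.3601       0.8092
   14162.1       0.3565       0.7814
   14435.2       0.3525       0.7546
   14713.6       0.3483       0.7286
   14997.3       0.3439       0.7034
   15286.4       0.3392       0.6791
   15581.2       0.3343       0.6556
   15881.6       0.3293       0.6328
   16187.9       0.3240       0.6108
   16500.0       0.3187       0.5895
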