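# Anomalous scattering coefficients for Ca (Z=20)
# Source: Cromer-Liberman relativistic calculation (as implemented in gemmi 0.7.4)
# Columns: energy_eV  f_prime_e  f_double_prime_e
# edge: K 4038.6
    1700.0      -0.5041       1.9020
    1732.8      -0.5240       1.8427
    1766.2      -0.5405       1.7852
    1800.2      -0.5614       1.7293
    1835.0      -0.5829       1.6749
    1870.3      -0.6048       1.6224
    1906.4      -0.6272       1.5712
    1943.2      -0.6500       1.5216
    1980.6      -0.6732       1.4736
    2018.8      -0.6969       1.4269
    2057.8      -0.7212       1.3816
    2097.4      -0.7458       1.3378
    2137.9      -0.7711       1.2952
    2179.1      -0.7968       1.2540
    2221.1      -0.8231       1.2140
    2263.9      -0.8500       1.1753
    2307.6      -0.8776       1.1376
    2352.1      -0.9059       1.1012
    2397.4      -0.9349       1.0659
    2443.7      -0.9648       1.0315
    2490.8      -0.9955       0.9984
    2538.8      -1.0273       0.9662
    2587.8      -1.0602       0.9350
    2637.7      -1.0943       0.9047
    2688.5      -1.1298       0.8755
    2740.4      -1.1668       0.8470
    2793.2      -1.2056       0.8196
    2847.1      -1.2463       0.7929
    2902.0      -1.2893       0.7671
    2957.9      -1.3348       0.7421
    3015.0      -1.3833       0.7177
    3073.1      -1.4352       0.6940
    3132.3      -1.4911       0.6711
    3192.7      -1.5518       0.6488
    3254.3      -1.6183       0.6273
    3317.1      -1.6916       0.6065
    3381.0      -1.7734       0.5863
    3446.2      -1.8659       0.5668
    3512.7      -1.9721       0.5479
    3580.4      -2.0964       0.5297
    3649.4      -2.2456       0.5120
    3719.8      -2.4313       0.4949
    3791.5      -2.6739       0.4784
    3864.6      -3.0176       0.4623
    3939.2      -3.5887       0.4468
    4013.6      -5.0931       0.4322
    4015.1      -5.1633       0.4319
    4030.6      -6.4245       0.4289
    4036.6      -8.2648       0.4278
    4038.1     -18.3973       4.0570
    4039.1      -8.7355       4.0551
    4040.6      -7.6722       4.0523
    4046.6      -6.2430       4.0411
    4063.6      -4.9406       4.0097
    4092.5      -4.0235       3.9575
    4171.4      -2.9133       3.8219
    4251.9      -2.3547       3.6961
    4333.9      -1.9474       3.5876
    4417.4      -1.6369       3.4819
    4502.6      -1.3867       3.3789
    4589.4      -1.1789       3.2787
    4677.9      -1.0021       3.1810
    4768.1      -0.8495       3.0859
    4860.1      -0.7161       2.9932
    4953.8      -0.5987       2.9031
    5049.3      -0.4945       2.8154
    5146.7      -0.4015       2.7300
    5245.9      -0.3184       2.6469
    5347.0      -0.2428       2.5660
    5450.1      -0.1755       2.4872
    5555.2      -0.1147       2.4106
    5662.4      -0.0598       2.3360
    5771.5      -0.0102       2.2636
    5882.8       0.0347       2.1931
    5996.3       0.0753       2.1246
    6111.9       0.1121       2.0581
    6229.7       0.1453       1.9934
    6349.8       0.1754       1.9305
    6472.3       0.2025       1.8694
    6597.1       0.2273       1.8101
    6724.3       0.2492       1.7524
    6854.0       0.2688       1.6964
    6986.1       0.2863       1.6420
    7120.8       0.3020       1.5892
    7258.1       0.3158       1.5379
    7398.1       0.3280       1.4881
    7540.7       0.3386       1.4398
    7686.1       0.3479       1.3928
    7834.3       0.3559       1.3473
    7985.4       0.3627       1.3031
    8139.4       0.3689       1.2602
    8296.3       0.3735       1.2186
    8456.3       0.3770       1.1782
    8619.3       0.3796       1.1391
    8785.5       0.3815       1.1011
    8954.9       0.3828       1.0643
    9127.6       0.3838       1.0283
    9303.6       0.3840       0.9935
    9483.0       0.3833       0.9598
    9665.9       0.3821       0.9272
    9852.2       0.3802       0.8956
   10042.2       0.3779       0.8650
   10235.8       0.3751       0.8355
   10433.2       0.3720       0.8069
   10634.4       0.3684       0.7792
   10839.4       0.3646       0.7524
   11048.4       0.3604       0.7265
   11261.5       0.3560       0.7014
   11478.6       0.3514       0.6771
   11700.0       0.3466       0.6536
   11925.6       0.3416       0.6309
   12155.5       0.3364       0.6090
   12389.9       0.3311       0.5878
   12628.8       0.3257       0.5672
   12872.3       0.3201       0.5474
   13120.5       0.3145       0.5282
   13373.5       0.3088       0.5096
   13631.4       0.3030       0.4917
   13894.2       0.2972       0.4744
   14162.1       0.2914       0.4576
   14435.2       0.2855       0.4414
   14713.6       0.2796       0.4257
   14997.3       0.2737       0.4106
   15286.4       0.2679       0.3960
   15581.2       0.2620       0.3819
   15881.6       0.2561       0.3682
   16187.9       0.2503       0.3550
   16500.0       0.2445       0.3423
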