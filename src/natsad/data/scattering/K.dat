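# Anomalous scattering coefficients for K (Z=19)
# Source: Cromer-Liberman relativistic calculation (as implemented in gemmi 0.7.4)
# Columns: energy_eV  f_prime_e  f_double_prime_e
# edge: K 3607.4
    1700.0      -0.6605       1.5345
    1732.8      -0.6832       1.4862
    1766.2      -0.7064       1.4394
    1800.2      -0.7300       1.3941
    1835.0      -0.7541       1.3500
    1870.3      -0.7786       1.3073
    1906.4      -0.8037       1.2659
    1943.2      -0.8293       1.2256
    1980.6      -0.8555       1.1868
    2018.8      -0.8822       1.1490
    2057.8      -0.9097       1.1123
    2097.4      -0.9378       1.0768
    2137.9      -0.9668       1.0423
    2179.1      -0.9965       1.0089
    2221.1      -1.0271       0.9766
    2263.9      -1.0588       0.9452
    2307.6      -1.0916       0.9148
    2352.1      -1.1256       0.8853
    2397.4      -1.1609       0.8568
    2443.7      -1.1979       0.8290
    2490.8      -1.2366       0.8022
    2538.8      -1.2772       0.7762
    2587.8      -1.3201       0.7510
    2637.7      -1.3656       0.7266
    2688.5      -1.4139       0.7029
    2740.4      -1.4658       0.6800
    2793.2      -1.5216       0.6578
    2847.1      -1.5823       0.6362
    2902.0      -1.6486       0.6154
    2957.9      -1.7216       0.5952
    3015.0      -1.8033       0.5756
    3073.1      -1.8955       0.5565
    3132.3      -2.0012       0.5380
    3192.7      -2.1249       0.5201
    3254.3      -2.2732       0.5027
    3317.1      -2.4570       0.4860
    3381.0      -2.6956       0.4697
    3446.2      -3.0307       0.4540
    3512.7      -3.5752       0.4388
    3580.4      -4.9321       0.4241
    3582.4      -5.0177       0.4237
    3599.4      -6.3041       0.4202
    3605.4      -7.8954       0.4189
    3606.9      -9.4969       0.4186
    3607.9      -9.5060       4.0659
    3609.4      -7.8910       4.0631
    3615.4      -6.2650       4.0518
    3632.4      -4.9075       4.0203
    3649.4      -4.2779       3.9892
    3719.8      -3.0552       3.8648
    3791.5      -2.4423       3.7457
    3864.6      -2.0164       3.6354
    3939.2      -1.6933       3.5279
    4015.1      -1.4348       3.4235
    4092.5      -1.2204       3.3217
    4171.4      -1.0384       3.2226
    4251.9      -0.8813       3.1261
    4333.9      -0.7443       3.0322
    4417.4      -0.6239       2.9409
    4502.6      -0.5169       2.8519
    4589.4      -0.4216       2.7654
    4677.9      -0.3363       2.6812
    4768.1      -0.2598       2.5994
    4860.1      -0.1907       2.5197
    4953.8      -0.1284       2.4423
    5049.3      -0.0721       2.3670
    5146.7      -0.0211       2.2938
    5245.9       0.0251       2.2226
    5347.0       0.0668       2.1534
    5450.1       0.1047       2.0861
    5555.2       0.1394       2.0207
    5662.4       0.1706       1.9571
    5771.5       0.1985       1.8954
    5882.8       0.2236       1.8354
    5996.3       0.2463       1.7770
    6111.9       0.2666       1.7204
    6229.7       0.2847       1.6654
    6349.8       0.3010       1.6120
    6472.3       0.3154       1.5601
    6597.1       0.3281       1.5097
    6724.3       0.3392       1.4608
    6854.0       0.3490       1.4133
    6986.1       0.3574       1.3673
    7120.8       0.3650       1.3225
    7258.1       0.3724       1.2791
    7398.1       0.3771       1.2369
    7540.7       0.3809       1.1959
    7686.1       0.3839       1.1563
    7834.3       0.3859       1.1178
    7985.4       0.3873       1.0805
    8139.4       0.3879       1.0444
    8296.3       0.3879       1.0094
    8456.3       0.3873       0.9755
    8619.3       0.3861       0.9426
    8785.5       0.3844       0.9108
    8954.9       0.3824       0.8799
    9127.6       0.3800       0.8498
    9303.6       0.3771       0.8207
    9483.0       0.3739       0.7925
    9665.9       0.3703       0.7652
    9852.2       0.3664       0.7389
   10042.2       0.3621       0.7133
   10235.8       0.3577       0.6887
   10433.2       0.3530       0.6648
   10634.4       0.3481       0.6417
   10839.4       0.3430       0.6194
   11048.4       0.3378       0.5978
   11261.5       0.3324       0.5769
   11478.6       0.3269       0.5567
   11700.0       0.3213       0.5372
   11925.6       0.3157       0.5183
   12155.5       0.3099       0.5001
   12389.9       0.3041       0.4825
   12628.8       0.2983       0.4654
   12872.3       0.2924       0.4490
   13120.5       0.2866       0.4330
   13373.5       0.2807       0.4176
   13631.4       0.2748       0.4028
   13894.2       0.2689       0.3884
   14162.1       0.2630       0.3745
   14435.2       0.2571       0.3611
   14713.6       0.2513       0.3482
   14997.3       0.2455       0.3357
   15286.4       0.2398       0.3236
   15581.2       0.2341       0.3119
   15881.6       0.2297       0.3006
   16187.9       0.2240       0.2897
   16500.0       0.2183       0.2791
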