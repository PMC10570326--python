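# Anomalous scattering coefficients for Cd (Z=48)
# Source: Cromer-Liberman relativistic calculation (as implemented in gemmi 0.7.4)
# Columns: energy_eV  f_prime_e  f_double_prime_e
# edge: L3 3537.5
# edge: L2 3727.0
# edge: L1 4018.0
    1700.0      -5.2320       9.5217
    1732.8      -5.2274       9.2707
    1766.2      -5.2281       9.0259
    1800.2      -5.2340       8.7870
    1835.0      -5.2452       8.5528
    1870.3      -5.2614       8.3253
    1906.4      -5.2827       8.1024
    1943.2      -5.3091       7.8848
    1980.6      -5.3404       7.6730
    2018.8      -5.3768       7.4659
    2057.8      -5.4191       7.2634
    2097.4      -5.4656       7.0666
    2137.9      -5.5177       6.8739
    2179.1      -5.5750       6.6862
    2221.1      -5.6381       6.5030
    2263.9      -5.7069       6.3244
    2307.6      -5.7821       6.1498
    2352.1      -5.8637       5.9798
    2397.4      -5.9522       5.8141
    2443.7      -6.0484       5.6520
    2490.8      -6.1457       5.4941
    2538.8      -6.2594       5.3401
    2587.8      -6.3830       5.1897
    2637.7      -6.5143       5.0432
    2688.5      -6.6610       4.9007
    2740.4      -6.8218       4.7615
    2793.2      -6.9980       4.6262
    2847.1      -7.1928       4.4943
    2902.0      -7.4091       4.3659
    2957.9      -7.6511       4.2410
    3015.0      -7.9245       4.1186
    3073.1      -8.2358       3.9981
    3132.3      -8.5975       3.8810
    3192.7      -9.0288       3.7670
    3254.3      -9.5558       3.6562
    3317.1     -10.2263       3.5484
    3381.0     -11.1358       3.4439
    3446.2     -12.5435       3.3421
    3512.5     -15.7996       3.2435
    3512.7     -15.8194       3.2432
    3529.5     -18.5735       3.2189
    3535.5     -21.9119       3.2103
    3537.0     -25.2413       3.2082
    3538.0     -25.2621      10.7627
    3539.5     -21.9287      10.7569
    3545.5     -18.6055      10.7336
    3562.5     -15.9209      10.6677
    3580.4     -14.7059      10.5984
    3649.4     -12.9987      10.3328
    3702.0     -13.3266      10.1322
    3719.0     -14.3286      10.0632
    3719.8     -14.4421      10.0597
    3725.0     -15.8918      10.0369
    3726.5     -17.5227      10.0304
    3727.5     -17.5179      13.7810
    3729.0     -15.8379      13.7728
    3735.0     -14.0946      13.7398
    3752.0     -12.5105      13.6471
    3791.5     -10.9481      13.4344
    3864.6      -9.4896      13.0509
    3939.2      -8.6904      12.6658
    3993.0      -8.7117      12.3897
    4010.0      -9.1964      12.3043
    4015.1      -9.7398      12.2788
    4016.0      -9.9493      12.2743
    4017.5     -10.7507      12.2669
    4018.5     -10.7443      14.1184
    4020.0      -9.9088      14.1105
    4026.0      -9.0265      14.0789
    4043.0      -8.1822      13.9898
    4092.5      -7.0852      13.7355
    4171.4      -6.0460      13.3446
    4251.9      -5.2740      12.9643
    4333.9      -4.6439      12.5947
    4417.4      -4.1094      12.2346
    4502.6      -3.6456      11.8832
    4589.4      -3.2384      11.5406
    4677.9      -2.8698      11.2053
    4768.1      -2.5485      10.8785
    4860.1      -2.2554      10.5599
    4953.8      -1.9970      10.2490
    5049.3      -1.7642       9.9464
    5146.7      -1.5540       9.6517
    5245.9      -1.3601       9.3650
    5347.0      -1.1885       9.0854
    5450.1      -1.0332       8.8133
    5555.2      -0.8927       8.5486
    5662.4      -0.7656       8.2910
    5771.5      -0.6509       8.0408
    5882.8      -0.5474       7.7973
    5996.3      -0.4540       7.5604
    6111.9      -0.3702       7.3303
    6229.7      -0.2950       7.1067
    6349.8      -0.2278       6.8893
    6472.3      -0.1680       6.6778
    6597.1      -0.1149       6.4724
    6724.3      -0.0682       6.2728
    6854.0      -0.0272       6.0787
    6986.1       0.0083       5.8904
    7120.8       0.0412       5.7072
    7258.1       0.0668       5.5292
    7398.1       0.0882       5.3563
    7540.7       0.1067       5.1884
    7686.1       0.1204       5.0254
    7834.3       0.1306       4.8671
    7985.4       0.1374       4.7135
    8139.4       0.1417       4.5644
    8296.3       0.1427       4.4198
    8456.3       0.1412       4.2794
    8619.3       0.1374       4.1434
    8785.5       0.1314       4.0113
    8954.9       0.1236       3.8829
    9127.6       0.1141       3.7577
    9303.6       0.1026       3.6363
    9483.0       0.0893       3.5188
    9665.9       0.0744       3.4049
    9852.2       0.0580       3.2946
   10042.2       0.0403       3.1877
   10235.8       0.0214       3.0841
   10433.2       0.0013       2.9838
   10634.4      -0.0197       2.8866
   10839.4      -0.0418       2.7926
   11048.4      -0.0646       2.7014
   11261.5      -0.0883       2.6131
   11478.6      -0.1127       2.5276
   11700.0      -0.1353       2.4448
   11925.6      -0.1612       2.3645
   12155.5      -0.1877       2.2869
   12389.9      -0.2128       2.2116
   12628.8      -0.2404       2.1387
   12872.3      -0.2686       2.0682
   13120.5      -0.2972       1.9998
   13373.5      -0.3263       1.9337
   13631.4      -0.3558       1.8697
   13894.2      -0.3858       1.8078
   14162.1      -0.4162       1.7478
   14435.2      -0.4470       1.6898
   14713.6      -0.4783       1.6336
   14997.3      -0.5102       1.5792
   15286.4      -0.5425       1.5266
   15581.2      -0.5734       1.4756
   15881.6      -0.6070       1.4262
   16187.9      -0.6394       1.3784
   16500.0      -0.6744       1.3321
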