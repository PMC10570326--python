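# Normal atomic form factors: 4-Gaussian-plus-constant fit
# f0(s) = sum_i a_i exp(-b_i s^2) + c,  s = sin(theta)/lambda [1/A]
# Source: International Tables for Crystallography Vol. C, Table 6.1.1.4 coefficients
# Columns: element a1 a2 a3 a4 b1 b2 b3 b4 c
H  0.4930 0.3229 0.1402 0.0408 10.5109 26.1257 3.1424 57.7997 0.0030
C  2.3100 1.0200 1.5886 0.8650 20.8439 10.2075 0.5687 51.6512 0.2156
N  12.2126 3.1322 2.0125 1.1663 0.0057 9.8933 28.9975 0.5826 -11.5290
O  3.0485 2.2868 1.5463 0.8670 13.2771 5.7011 0.3239 32.9089 0.2508
S  6.9053 5.2034 1.4379 1.5863 1.4679 22.2151 0.2536 56.1720 0.8669
P  6.4345 4.1791 1.7800 1.4908 1.9067 27.1570 0.5260 68.1645 1.1149
Ca 8.6266 7.3873 1.5899 1.0211 10.4421 0.6599 85.7484 178.4370 1.3751
K  8.2186 7.4398 1.0519 0.8659 12.7949 0.7748 213.1870 41.6841 1.4228
Cl 11.4604 7.1964 6.2556 1.6455 0.0104 1.1662 18.5194 47.7784 -9.5574
Zn 14.0743 7.0318 5.1652 2.4100 3.2655 0.2333 10.3163 58.7097 1.3041
Cd 19.2214 17.6444 4.4610 1.6029 0.5946 6.9089 24.7008 87.4825 5.0694
I  20.1472 18.9949 7.5138 2.2735 4.3470 0.3814 27.7660 66.8776 4.0712
V  10.2971 7.3511 2.0703 2.0571 6.8657 0.4385 26.8938 102.4780 1.2199
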