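# Station-level ingestion hazard quotients (published survey values).
# Exponent restorations: S1 BBP; S2 BBP
station,DMP,DEP,IBP,DBP,BBP,DOP
1,7.1429e-10,3.69517e-08,7.5602e-07,6.47538e-07,6.9301e-08,1.22229e-07
2,6.9978e-08,8.0881e-08,4.08551e-06,4.17387e-06,6.40688e-08,3.2727e-07
3,6.6075e-09,3.34798e-08,4.94645e-06,5.46871e-06,8.29505e-08,2.00924e-07
4,1.1951e-08,2.7024e-08,2.18061e-07,4.78852e-07,4.02545e-08,1.32351e-07
5,1.7049e-07,1.44523e-07,4.14594e-07,3.98485e-07,1.38991e-07,1.01307e-07
6,1.7103e-08,3.34162e-08,1.83467e-05,6.24538e-07,2.62507e-07,1.18438e-06
7,3.0991e-08,2.86299e-08,1.22184e-07,1.50492e-07,4.41888e-08,6.84937e-08
8,7.1429e-10,1.52385e-08,2.89209e-07,6.54481e-07,3.76307e-08,2.25068e-08
9,5.8571e-09,1.79944e-08,2.35565e-07,3.7173e-07,3.32064e-08,1.10116e-07
10,7.1429e-10,3.0739e-08,4.41638e-07,4.40063e-07,4.06648e-08,1.31461e-07
11,8.852e-09,2.22761e-08,2.09815e-07,2.25849e-07,1.52712e-07,3.95083e-08
12,1.067e-08,1.95491e-08,2.21514e-07,1.95577e-07,6.03945e-08,1.25987e-07
13,7.1429e-10,1.71074e-08,4.86932e-07,8.98752e-07,3.57555e-08,1.78063e-07
14,7.1429e-09,2.22183e-08,2.59805e-07,1.96182e-07,4.92919e-08,2.879e-08
15,5e-09,1.61945e-08,8.78844e-07,7.08329e-07,3.27112e-08,1.44414e-07
Mean,2.143e-08,3.57143e-08,2.1345e-06,1.07143e-06,7.1429e-08,1.96429e-07
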