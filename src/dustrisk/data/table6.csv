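# Station-level dermal hazard quotients (published survey values).
# Exponent restorations: S1 DOP; S6 DOP; Mean DBP
station,DMP,DEP,IBP,DBP,BBP,DOP
1,4e-12,2.0693e-10,4.23371e-09,3.62621e-09,3.88085e-10,6.8448e-10
2,3.91877e-10,4.52933e-10,2.28789e-08,2.33737e-08,3.58785e-10,1.83271e-09
3,3.70021e-11,1.87487e-10,2.77001e-08,3.06248e-08,4.64523e-10,1.12517e-09
4,6.69269e-11,1.51335e-10,1.22114e-09,2.68157e-09,2.25425e-10,7.41167e-10
5,9.54741e-10,8.0933e-10,2.32172e-09,2.23152e-09,7.78352e-10,5.67319e-10
6,9.5776e-11,1.87131e-10,1.02742e-07,3.49741e-09,1.47004e-09,6.63253e-09
7,1.73551e-10,1.60328e-10,6.84229e-10,8.42757e-10,2.47457e-10,3.83565e-10
8,4e-12,8.53357e-11,1.61957e-09,3.66509e-09,2.10732e-10,1.26038e-10
9,3.28e-11,1.00769e-10,1.31917e-09,2.08169e-09,1.85956e-10,6.16651e-10
10,4e-12,1.72138e-10,2.47317e-09,2.46435e-09,2.27723e-10,7.3618e-10
11,4.95709e-11,1.24746e-10,1.17496e-09,1.26475e-09,8.55185e-10,2.21247e-10
12,5.9752e-11,1.09475e-10,1.24048e-09,1.09523e-09,3.38209e-10,7.05527e-10
13,4e-12,9.58017e-11,2.72682e-09,5.03301e-09,2.00231e-10,9.97153e-10
14,4e-11,1.24422e-10,1.45491e-09,1.09862e-09,2.76035e-10,1.61224e-10
15,2.8e-11,9.06893e-11,4.92153e-09,3.96664e-09,1.83183e-10,8.0872e-10
Mean,1.2e-10,2e-10,1.19531e-08,6e-09,4e-10,1.1e-09
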