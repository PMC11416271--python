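# Station-level BBP cancer risks per pathway (published survey values).
station,cr_inh,cr_ing,cr_der
1,4.99737e-15,2.16447e-11,1.2121e-13
2,4.62008e-15,2.00105e-11,1.12059e-13
3,5.98166e-15,2.59078e-11,1.45084e-13
4,2.9028e-15,1.25726e-11,7.04068e-14
5,1.00228e-14,4.3411e-11,2.43102e-13
6,1.89297e-14,8.19885e-11,4.59136e-13
7,3.18651e-15,1.38014e-11,7.7288e-14
8,2.7136e-15,1.17532e-11,6.58177e-14
9,2.39456e-15,1.03713e-11,5.80794e-14
10,2.93238e-15,1.27008e-11,7.11243e-14
11,1.10122e-14,4.76962e-11,2.67099e-13
12,4.35512e-15,1.88629e-11,1.05633e-13
13,2.57837e-15,1.11675e-11,6.25378e-14
14,3.5545e-15,1.53953e-11,8.62136e-14
15,2.35884e-15,1.02166e-11,5.72132e-14
Mean,5.5027e-15,2.38334e-11,1.33467e-13
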