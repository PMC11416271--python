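# Station-level hazard indices (published survey values).
station,DMP,DEP,IBP,DBP,BBP,DOP
1,7.18451e-10,3.71672e-08,7.60366e-07,6.51183e-07,6.9693e-08,1.22941e-07
2,7.03861e-08,8.13526e-08,4.10899e-06,4.19737e-06,6.44313e-08,3.29179e-07
3,6.64605e-09,3.3675e-08,4.97488e-06,5.4995e-06,8.34198e-08,2.02095e-07
4,1.20209e-08,2.71816e-08,2.19314e-07,4.81548e-07,4.04823e-08,1.33123e-07
5,1.71484e-07,1.45366e-07,4.16977e-07,4.00728e-07,1.39778e-07,1.01898e-07
6,1.72026e-08,3.3611e-08,1.84522e-05,6.28054e-07,2.63992e-07,1.19129e-06
7,3.1172e-08,2.87969e-08,1.22886e-07,1.51339e-07,4.44388e-08,6.88931e-08
8,7.18451e-10,1.53274e-08,2.90872e-07,6.58165e-07,3.78436e-08,2.2638e-08
9,5.8913e-09,1.80993e-08,2.36919e-07,3.73822e-07,3.33943e-08,1.10758e-07
10,7.18451e-10,3.09182e-08,4.44176e-07,4.4254e-07,4.08948e-08,1.32227e-07
11,8.90357e-09,2.2406e-08,2.11021e-07,2.2712e-07,1.53576e-07,3.97387e-08
12,1.07322e-08,1.96631e-08,2.22787e-07,1.96678e-07,6.07362e-08,1.26722e-07
13,7.18451e-10,1.72072e-08,4.89731e-07,9.03811e-07,3.59578e-08,1.79101e-07
14,7.18451e-09,2.23478e-08,2.61298e-07,1.97286e-07,4.95708e-08,2.89579e-08
15,5.02915e-09,1.6289e-08,8.83895e-07,7.12316e-07,3.28963e-08,1.45256e-07
Mean,2.1554e-08,3.59225e-08,2.14676e-06,1.07746e-06,7.1833e-08,1.97574e-07
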