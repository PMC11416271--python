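# Summary (min/max/mean/SD over 15 stations) of dust concentrations
# in ug/g per compound and sampling step, published Yazd survey.
# Zero minima are below-LOD censored records printed as 0.00.
compound,step,min,max,mean,sd,allowable
DMP,R1,0.0,2.387,0.305,0.631,0.02
DMP,R2,0.0,3.403,0.325,0.868,0.02
DMP,R3,0.0,1.82,0.333,0.529,0.02
DEP,R1,0.017,0.162,0.041,0.038,0.071
DEP,R2,0.075,0.242,0.128,0.05,0.071
DEP,R3,0.05,1.43,0.178,0.349,0.071
DBP,R1,0.021,0.766,0.146,0.22,0.081
DBP,R2,0.054,0.276,0.118,0.065,0.081
DBP,R3,0.06,0.45,0.116,0.098,0.081
IBP,R1,0.088,13.151,1.525,3.385,
IBP,R2,0.234,1.944,0.559,0.426,
IBP,R3,0.22,7.0,1.062,1.898,
BBP,R1,0.009,0.074,0.021,0.018,1.22
BBP,R2,0.0,0.197,0.039,0.049,1.22
BBP,R3,0.0,0.13,0.033,0.034,1.22
BEHP,R1,1.032,185.432,17.267,46.698,4.35
BEHP,R2,0.368,326.211,24.24,83.564,4.35
BEHP,R3,0.087,256.0,20.193,55.308,4.35
DOP,R1,0.013,0.663,0.109,0.162,1.2
DOP,R2,0.0,3.609,0.275,0.923,1.2
DOP,R3,0.0,25.0,3.848,14.161,1.2
DiOP,R1,0.347,1.189,0.57,0.232,
DiOP,R2,0.037,0.25,0.088,0.056,
DiOP,R3,0.048,1.1,0.323,0.247,
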