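# Station-level inhalation hazard quotients from the published Yazd
# industrial-park outdoor-dust survey. Column labels IBP/DBP correspond
# to the published DIBP/DnBP. Exponents proven wrong by the survey's own
# internal identities (HI additivity, pathway-ratio constancy) were
# restored: S2 DBP; S3 DBP; S6 DOP
station,DMP,DEP,IBP,DBP,BBP,DOP
1,1.6492e-13,8.5315e-12,1.11713e-10,1.86881e-11,4.00009e-12,2.822e-11
2,1.6157e-11,1.8674e-11,6.03694e-10,1.20459e-10,3.69809e-12,7.55609e-11
3,1.5256e-12,7.7299e-12,7.3091e-10,1.57829e-10,4.78795e-12,4.63898e-11
4,2.7593e-12,6.23938e-12,3.22217e-11,1.38198e-11,2.32351e-12,3.05576e-11
5,3.9363e-11,3.33679e-11,6.12623e-11,1.15004e-11,8.02267e-12,2.339e-11
6,3.9487e-12,7.71521e-12,2.711e-09,1.80244e-11,1.51521e-11,2.73453e-10
7,7.1554e-12,6.61015e-12,1.80545e-11,4.34325e-12,2.5506e-12,1.5814e-11
8,1.6492e-13,3.5183e-12,4.27349e-11,1.88885e-11,2.17207e-12,5.19642e-12
9,1.3523e-12,4.15459e-12,3.48083e-11,1.07282e-11,1.91669e-12,2.54239e-11
10,1.6492e-13,7.09709e-12,6.52585e-11,1.27003e-11,2.34719e-12,3.0352e-11
11,2.0438e-12,5.14317e-12,3.10032e-11,6.51806e-12,8.81461e-12,9.12178e-12
12,2.4635e-12,4.51354e-12,3.2732e-11,5.6444e-12,3.48601e-12,2.90882e-11
13,1.6492e-13,3.94981e-12,7.19513e-11,2.59383e-11,2.06383e-12,4.11116e-11
14,1.6492e-12,5.12981e-12,3.839e-11,5.66187e-12,2.84516e-12,6.6471e-12
15,1.1544e-12,3.73903e-12,1.29862e-10,2.04426e-11,1.88811e-12,3.33427e-11
Mean,4.947e-12,8.2458e-12,3.15402e-10,3.09217e-11,4.1229e-12,4.5352e-11
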