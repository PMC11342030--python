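compound,mean,std,min,max
Naph,1.65,0.62,0.72,2.03
Acy,3.36,2.39,1.05,6.5
Acen,5.36,4.52,2.27,12.01
Fln,10.81,7.84,3.96,18.13
Phe,3.55,1.33,2,4.92
Ant,3.38,2.42,0.98,6.03
Flt,5.17,3.14,2.29,8.93
Pyr,6.67,6.88,1.18,16.05
BbF,17.30,14.06,4,31.03
BkF,17.53,10.43,4.01,27.92
CHR,3.24,1.71,1.54,4.84
BaP,5.39,5.69,0.26,11.15
BaA,2.45,2.02,0.62,4.9
IcP,5.83,4.58,1.97,12.04
DhA,6.68,2.50,5.04,10.38
BgP,0,0.00,0,0
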