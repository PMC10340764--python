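residue,name,raw,stir_frying,bran_stir_frying
T,Thr,2.39,2.18,2.24
V,Val,4.87,4.71,4.74
M,Met,1.13,1.42,1.19
I,Ile,3.41,3.32,3.32
L,Leu,17.62,17.46,17.17
F,Phe,5.75,5.55,5.68
K,Lys,0.14,0.10,0.11
W,Trp,0,0,0
D,Asp,5.98,5.99,5.89
Y,Tyr,4.81,4.73,4.76
S,Ser,4.62,4.68,4.54
E,Glu,27.29,27.10,26.64
G,Gly,0.57,0.70,0.61
A,Ala,12.38,12.50,12.19
H,His,1.12,1.09,1.08
R,Arg,2.23,2.23,2.15
P,Pro,8.34,8.20,8.22
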