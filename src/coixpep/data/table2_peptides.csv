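sequence,mol_weight,bioactivity,dppiv_probability,allergen_mark,caco2_log,mdck_cm_s,hia_band,ppb_percent,bbb_band,fu_percent
WGF,408.18,0.997,0.114,*,-6.147,8.90 × 10^-6,---,67.13%,-,41.60%
PF,262.13,0.993,0.120,*,-5.911,1.70 × 10^-5,++,16.74%,-,75.73%
PPF,359.18,0.989,0.117,*,-5.979,2.40 × 10^-5,+++,22.82%,--,73.78%
AF,236.12,0.973,0.049,#,-6.109,0.0011,---,15.81%,++,75.64%
QMPF,521.23,0.971,0.103,*,-6.277,9.60 × 10^-6,++,17.36%,--,69.34%
IF,278.16,0.949,0.101,#,-5.891,0.00014,---,50.43%,++,43.75%
SF,252.11,0.949,NA,#,-6.168,0.0034,---,12.01%,++,80.45%
VMPF,492.24,0.941,0.120,*,-6.387,1.40 × 10^-5,++,33.07%,---,57.91%
PSMCGL,606.25,0.900,NA,*,-6.928,2.50 × 10^-6,+++,15.43%,---,77.17%
ML,262.14,0.895,0.049,#,-5.803,2.00 × 10^-5,---,9.38%,--,81.31%
PCNPL,542.25,0.858,0.126,*,-6.576,1.30 × 10^-5,+++,9.90%,---,79.71%
MAPQIF,705.35,0.834,0.060,#,-6.385,2.90 × 10^-5,+++,39.54%,---,52.31%
PL,228.15,0.811,0.425,*,-5.667,8.00 × 10^-5,-,7.64%,--,84.36%
SWQQPIVGGVGF,1273.65,0.768,-,*,-5.645,2.20 × 10^-5,++,55.93%,---,40.33%
PPVSAIGF,786.43,0.766,NA,#,-6.928,2.30 × 10^-5,+++,37.20%,---,56.18%
QMMMQL,780.33,0.758,0.050,#,-6.353,7.50 × 10^-6,---,18.75%,---,65.28%
QQF,421.2,0.718,0.106,#,-5.960,0.00038,---,12.74%,-,73.26%
MNPAL,544.27,0.710,0.126,*,-6.605,2.00 × 10^-5,-,8.99%,---,80.78%
QQALLGGALF,1016.57,0.689,-,#,-6.173,5.10 × 10^-5,+,22.95%,---,50.89%
MAL,333.17,0.681,0.119,*,-6.128,2.00 × 10^-5,---,7.45%,--,81.85%
AAAF,378.19,0.677,0.113,#,-6.593,0.00081,---,12.58%,-,75.18%
AAASPAAF,704.35,0.665,0.020,*,-7.140,0.00065,+++,17.31%,---,66.54%
PSNPL,526.28,0.656,0.142,*,-6.617,0.00026,++,13.12%,---,85.01%
QQCNPL,701.32,0.646,0.042,*,-6.271,0.00014,--,9.44%,---,79.38%
PHVSAIGF,826.43,0.638,NA,#,-6.730,2.70 × 10^-6,+++,35.05%,---,54.75%
PAL,299.18,0.632,0.724,#,-6.019,0.00017,++,9.22%,--,84.24%
YPQAMANIAAF,1195.57,0.627,-,*,-6.449,2.80 × 10^-5,+++,44.34%,---,39.59%
QPYR,562.29,0.616,NA,*,-6.666,0.00014,++,12.15%,--,71.84%
QPQCSCSPVAVPYYAQQR,2023.92,0.613,-,*,-6.751,3.00 × 10^-5,+++,36.26%,---,35.62%
PSYCGTTPSCAVSAAIPPYY,2046.91,0.610,-,*,-8.250,3.80 × 10^-6,+++,60.25%,---,30.74%
NCHEF,648.23,0.596,NA,#,-6.747,7.40 × 10^-6,---,19.09%,--,72.76%
AGL,259.15,0.593,0.153,#,-6.478,0.0024,---,4.47%,+,87.34%
YPQAL,590.31,0.586,0.082,*,-6.457,0.00036,++,22.71%,---,68.21%
APTAAIIPR,908.54,0.584,-,*,-7.028,8.70 × 10^-5,+++,28.99%,---,58.13%
QPYSL,606.3,0.567,0.066,#,-6.680,0.0006,++,16.25%,--,73.57%
YPCAEYL,857.36,0.564,NA,#,-7.080,7.10 × 10^-6,+++,42.10%,---,48.35%
SSPL,402.21,0.550,0.362,*,-6.599,0.005,+,9.00%,--,88.11%
PSL,315.18,0.540,0.380,#,-6.222,0.001,++,9.61%,--,87.55%
NPAASCQQPIVGAAL,1438.72,0.535,-,#,-6.761,0.00012,+++,21.70%,---,53.67%
QGL,316.17,0.533,0.254,*,-6.422,0.0011,---,4.61%,+,85.41%
ASNPL,500.26,0.525,0.119,#,-6.894,0.0012,--,8.17%,--,86.93%
QQPL,484.26,0.523,0.469,*,-6.037,0.00036,--,8.26%,--,82.93%
QQHQPPPPQK,1183.61,0.518,-,*,-5.456,8.70 × 10^-5,+++,25.09%,---,61.34%
AAANPAAYL,860.44,0.515,NA,*,-7.132,0.00015,++,22.84%,---,60.16%
CSYSYYSGNSNL,1356.53,0.507,-,*,-8.364,0.00012,-,27.60%,---,54.05%
VNF,378.19,0.505,0.113,*,-6.443,0.00067,---,10.57%,+,73.09%
AQQPL,555.3,0.505,0.297,*,-6.276,0.00029,--,8.93%,--,81.48%
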