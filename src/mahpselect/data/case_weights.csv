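trait,si,sibh,rg_yld_n,rg_tss_n,rg_yld_s,rg_tss_s,ega_n,ega_s,final_weight
DTF,0.096,0.540,-0.224,0.075,0.027,0.099,0.018,0.038,0.668
DFF,0.078,0.298,-0.139,0.028,0.039,0.100,0.027,0.030,0.461
DTH,0.056,0.231,-0.063,0.119,0.021,0.142,0.028,0.024,0.560
Yld,0.044,0.246,0.371,-0.118,0.160,0.028,0.190,0.238,1.160
SFW,0.207,0.022,0.704,-0.240,0.961,-0.174,0.036,0.004,1.520
SFV,0.247,0.226,0.345,-0.129,0.147,0.011,0.627,0.692,2.167
FD,0.192,0.235,-0.300,0.202,-0.148,0.038,0.447,0.385,1.051
FWC,0.055,0.230,0.094,-0.095,-0.018,0.027,0.141,0.125,0.560
SPAD,0.022,0.230,0.034,0.005,-0.014,-0.047,0.118,0.095,0.443
pH,0.082,0.229,0.052,0.011,0.017,-0.053,0.167,0.185,0.690
EC,0.225,0.228,-0.075,0.420,0.003,0.426,0.255,0.225,1.707
TDS,0.222,0.229,-0.074,0.422,0.003,0.428,0.252,0.222,1.704
Sal,0.233,0.229,-0.074,0.420,0.001,0.426,0.252,0.223,1.710
TSS,0.125,0.229,-0.078,0.557,0.007,0.605,0.307,0.305,2.057
RWC,0.812,0.178,0.221,-0.007,0.064,-0.093,0.139,0.104,1.417
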