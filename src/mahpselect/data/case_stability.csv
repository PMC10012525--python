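trait,si,sibh,rg_yld_n,rg_tss_n,rg_yld_s,rg_tss_s
DTF,0.087,2.359,-0.604,0.134,0.169,0.163
DFF,0.070,1.304,-0.374,0.050,0.242,0.165
DTH,0.051,1.010,-0.170,0.214,0.132,0.235
Yld,0.040,1.076,1.000,-0.211,1.000,0.046
SFW,0.187,0.094,1.000,-0.430,0.992,-0.287
SFV,0.223,0.987,0.931,-0.232,0.916,0.019
FD,0.173,1.025,-0.808,0.363,-0.922,0.062
FWC,0.050,1.006,0.253,-0.171,-0.114,0.045
SPAD,0.020,1.006,0.091,0.009,-0.087,-0.077
pH,0.074,1.000,0.140,0.019,0.108,-0.088
EC,0.203,0.998,-0.203,0.754,0.016,0.705
TDS,0.200,1.002,-0.200,0.758,0.017,0.708
Sal,0.210,0.999,-0.200,0.754,0.008,0.705
TSS,0.113,1.000,-0.211,1.000,0.046,1.000
RWC,0.733,0.776,0.596,-0.012,0.401,-0.154
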