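trait,ms_replication,ms_families,ms_error,sig_replication,sig_families,h2_printed,ega_pct_printed
DTF,218.690,134.679,80.589,,a,0.402,8.003
DFF,211.480,125.251,73.366,,b,0.414,6.334
DTH,14.368,44.377,4.577,a,b,0.897,5.150
H,227.468,2375.152,3293.174,,,,
CN,30.037,1591.293,1991.688,,,,
FN,1.803,124.455,154.764,,,,
Yld,8475.547,999824.592,112924.005,,b,0.887,50.721
SFW,85.938,406.842,397.958,,,0.022,0.775
SFV,235.887,18095.968,306.065,,b,0.983,147.304
FD,0.017,0.657,0.014,,b,0.978,82.017
FWC,31.146,90.521,9.696,a,b,0.893,26.680
SPAD,54.415,157.793,16.842,a,b,0.893,20.235
pH,0.271,2.969,0.329,,b,0.889,39.370
EC,0.833,9.003,1.011,,b,0.888,47.776
TDS,0.228,2.512,0.277,,b,0.890,47.313
Sal,0.289,3.134,0.349,,b,0.889,47.531
TSS,1.718,18.659,2.081,,b,0.888,64.804
RWC,0.006,0.036,0.010,,b,0.720,22.042
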