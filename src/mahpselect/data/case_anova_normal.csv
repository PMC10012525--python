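trait,ms_replication,ms_families,ms_error,sig_replication,sig_families,h2_printed,ega_pct_printed
DTF,207.462,140.670,116.718,,,0.170,3.474
DFF,124.936,149.298,101.864,,a,0.318,5.320
DTH,12.848,53.089,5.925,,b,0.888,5.556
H,27821.134,6432.100,7955.570,a,,,
CN,19490.528,4202.610,5145.226,a,,,
FN,1672.741,303.535,379.873,a,,,
Yld,215637.324,3147800.590,552932.699,,b,0.824,37.292
SFW,6144.584,985.280,1214.939,b,,,
SFV,1084.634,53080.267,206.868,b,b,0.996,123.350
FD,0.085,0.513,0.023,a,b,0.954,87.949
FWC,2.110,117.172,13.219,,b,0.887,27.805
SPAD,3.506,208.135,23.396,,b,0.888,23.163
pH,0.187,2.276,0.252,,b,0.889,32.911
EC,0.798,9.750,1.078,,b,0.889,50.153
TDS,0.226,2.707,0.304,,b,0.888,49.494
Sal,0.275,3.320,0.368,,b,0.889,49.538
TSS,1.351,16.396,1.826,,b,0.889,60.426
RWC,0.004,0.045,0.003,,b,0.928,27.237
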