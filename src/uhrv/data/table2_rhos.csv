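# Spearman rank correlations between each ultra-short feature and its 5-min
# equivalent, per phase (rest/stress) and ultra-short scale (seconds).
# All printed correlations were reported significant (p_rho < 0.05); exact
# p-values are not printed, so p_rho carries a nominal 0.001 stand-in.
# Cells where the feature is not computable at the scale are omitted.
feature,scale_s,phase,rho,p_rho
MeanNN,180,rest,0.984,0.001
MeanNN,120,rest,0.890,0.001
MeanNN,60,rest,0.975,0.001
MeanNN,30,rest,0.936,0.001
MeanNN,180,stress,0.985,0.001
MeanNN,120,stress,0.937,0.001
MeanNN,60,stress,0.955,0.001
MeanNN,30,stress,0.964,0.001
StdNN,180,rest,0.954,0.001
StdNN,120,rest,0.875,0.001
StdNN,60,rest,0.905,0.001
StdNN,30,rest,0.749,0.001
StdNN,180,stress,0.962,0.001
StdNN,120,stress,0.912,0.001
StdNN,60,stress,0.791,0.001
StdNN,30,stress,0.640,0.001
MeanHR,180,rest,0.984,0.001
MeanHR,120,rest,0.891,0.001
MeanHR,60,rest,0.975,0.001
MeanHR,30,rest,0.947,0.001
MeanHR,180,stress,0.985,0.001
MeanHR,120,stress,0.938,0.001
MeanHR,60,stress,0.954,0.001
MeanHR,30,stress,0.964,0.001
StdHR,180,rest,0.914,0.001
StdHR,120,rest,0.789,0.001
StdHR,60,rest,0.796,0.001
StdHR,30,rest,0.635,0.001
StdHR,180,stress,0.971,0.001
StdHR,120,stress,0.904,0.001
StdHR,60,stress,0.784,0.001
StdHR,30,stress,0.696,0.001
RMSSD,180,rest,0.961,0.001
RMSSD,120,rest,0.914,0.001
RMSSD,60,rest,0.946,0.001
RMSSD,30,rest,0.859,0.001
RMSSD,180,stress,0.983,0.001
RMSSD,120,stress,0.928,0.001
RMSSD,60,stress,0.915,0.001
RMSSD,30,stress,0.852,0.001
NN50,180,rest,0.972,0.001
NN50,120,rest,0.883,0.001
NN50,60,rest,0.949,0.001
NN50,30,rest,0.822,0.001
NN50,180,stress,0.971,0.001
NN50,120,stress,0.920,0.001
NN50,60,stress,0.905,0.001
NN50,30,stress,0.894,0.001
pNN50,180,rest,0.967,0.001
pNN50,120,rest,0.882,0.001
pNN50,60,rest,0.943,0.001
pNN50,30,rest,0.818,0.001
pNN50,180,stress,0.969,0.001
pNN50,120,stress,0.915,0.001
pNN50,60,stress,0.913,0.001
pNN50,30,stress,0.881,0.001
LF,180,rest,0.894,0.001
LF,120,rest,0.886,0.001
LF,180,stress,0.921,0.001
LF,120,stress,0.916,0.001
HF,180,rest,0.915,0.001
HF,120,rest,0.906,0.001
HF,60,rest,0.901,0.001
HF,180,stress,0.925,0.001
HF,120,stress,0.915,0.001
HF,60,stress,0.798,0.001
LF/HF,180,rest,0.830,0.001
LF/HF,120,rest,0.839,0.001
LF/HF,180,stress,0.846,0.001
LF/HF,120,stress,0.807,0.001
TotPow,180,rest,0.897,0.001
TotPow,120,rest,0.882,0.001
TotPow,180,stress,0.900,0.001
TotPow,120,stress,0.905,0.001
SD1,180,rest,0.961,0.001
SD1,120,rest,0.914,0.001
SD1,60,rest,0.945,0.001
SD1,30,rest,0.862,0.001
SD1,180,stress,0.983,0.001
SD1,120,stress,0.928,0.001
SD1,60,stress,0.915,0.001
SD1,30,stress,0.852,0.001
SD2,180,rest,0.956,0.001
SD2,120,rest,0.865,0.001
SD2,60,rest,0.876,0.001
SD2,30,rest,0.707,0.001
SD2,180,stress,0.941,0.001
SD2,120,stress,0.898,0.001
SD2,60,stress,0.755,0.001
SD2,30,stress,0.694,0.001
ApEn,180,rest,0.771,0.001
ApEn,120,rest,0.169,0.001
ApEn,180,stress,0.918,0.001
ApEn,120,stress,0.790,0.001
SampEn,180,rest,0.855,0.001
SampEn,120,rest,0.666,0.001
SampEn,60,rest,0.681,0.001
SampEn,180,stress,0.931,0.001
SampEn,120,stress,0.826,0.001
SampEn,60,stress,0.599,0.001
D2,180,rest,0.922,0.001
D2,120,rest,0.674,0.001
D2,60,rest,0.330,0.001
D2,180,stress,0.967,0.001
D2,120,stress,0.876,0.001
D2,60,stress,0.816,0.001
dfa1,180,rest,0.661,0.001
dfa1,120,rest,0.687,0.001
dfa1,60,rest,0.637,0.001
dfa1,180,stress,0.927,0.001
dfa1,120,stress,0.908,0.001
dfa1,60,stress,0.799,0.001
dfa2,180,rest,0.633,0.001
dfa2,120,rest,0.611,0.001
dfa2,60,rest,0.673,0.001
dfa2,180,stress,0.767,0.001
dfa2,120,stress,0.563,0.001
dfa2,60,stress,0.485,0.001
RPlmean,180,rest,0.837,0.001
RPlmean,120,rest,0.708,0.001
RPlmean,60,rest,0.645,0.001
RPlmean,180,stress,0.901,0.001
RPlmean,120,stress,0.730,0.001
RPlmean,60,stress,0.503,0.001
RPlmax,180,rest,0.738,0.001
RPlmax,120,rest,0.588,0.001
RPlmax,60,rest,0.583,0.001
RPlmax,180,stress,0.896,0.001
RPlmax,120,stress,0.737,0.001
RPlmax,60,stress,0.678,0.001
REC,180,rest,0.880,0.001
REC,120,rest,0.643,0.001
REC,60,rest,0.608,0.001
REC,180,stress,0.892,0.001
REC,120,stress,0.689,0.001
REC,60,stress,0.513,0.001
RPadet,180,rest,0.852,0.001
RPadet,120,rest,0.645,0.001
RPadet,60,rest,0.495,0.001
RPadet,180,stress,0.948,0.001
RPadet,120,stress,0.817,0.001
RPadet,60,stress,0.642,0.001
ShanEn,180,rest,0.795,0.001
ShanEn,120,rest,0.661,0.001
ShanEn,60,rest,0.614,0.001
ShanEn,180,stress,0.907,0.001
ShanEn,120,stress,0.720,0.001
ShanEn,60,stress,0.463,0.001
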