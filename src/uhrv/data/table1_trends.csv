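# Stress-vs-rest median trend codes per feature and nominal scale (seconds).
# SIG_DOWN/SIG_UP: significant (p < 0.05) decrease/increase under stress;
# NS_DOWN/NS_UP: non-significant; NA: feature not computable at that scale.
# Two cells in the flattened source table are typographically ambiguous
# (pNN50 at 180 s; RPlmax at 300/180 s); they are resolved here from the
# per-scale significance tallies stated in the accompanying results text
# (300 s: 18 significant, 12 down, 6 up; 180 s: 12 down, 5 up, RPlmax
# significant since it "loses" significance at 120 s; 120 s: 15; 60 s: 10).
feature,scale_s,code
MeanNN,300,SIG_DOWN
MeanNN,180,SIG_DOWN
MeanNN,120,SIG_DOWN
MeanNN,60,SIG_DOWN
MeanNN,30,SIG_DOWN
StdNN,300,SIG_DOWN
StdNN,180,SIG_DOWN
StdNN,120,SIG_DOWN
StdNN,60,SIG_DOWN
StdNN,30,SIG_DOWN
MeanHR,300,SIG_UP
MeanHR,180,SIG_UP
MeanHR,120,SIG_UP
MeanHR,60,SIG_UP
MeanHR,30,SIG_UP
StdHR,300,SIG_UP
StdHR,180,SIG_UP
StdHR,120,SIG_UP
StdHR,60,SIG_UP
StdHR,30,SIG_UP
RMSSD,300,NS_UP
RMSSD,180,NS_UP
RMSSD,120,NS_UP
RMSSD,60,NS_UP
RMSSD,30,NS_DOWN
NN50,300,NS_UP
NN50,180,NS_UP
NN50,120,NS_UP
NN50,60,NS_UP
NN50,30,NS_UP
pNN50,300,SIG_DOWN
pNN50,180,NS_UP
pNN50,120,NS_DOWN
pNN50,60,NS_DOWN
pNN50,30,NS_DOWN
LF,300,SIG_DOWN
LF,180,SIG_DOWN
LF,120,SIG_DOWN
LF,60,NA
LF,30,NA
HF,300,SIG_DOWN
HF,180,SIG_DOWN
HF,120,SIG_DOWN
HF,60,SIG_DOWN
HF,30,NA
LF/HF,300,SIG_DOWN
LF/HF,180,SIG_DOWN
LF/HF,120,SIG_DOWN
LF/HF,60,NA
LF/HF,30,NA
TotPow,300,SIG_DOWN
TotPow,180,SIG_DOWN
TotPow,120,SIG_DOWN
TotPow,60,NA
TotPow,30,NA
SD1,300,NS_UP
SD1,180,NS_UP
SD1,120,NS_UP
SD1,60,NS_UP
SD1,30,NS_DOWN
SD2,300,SIG_DOWN
SD2,180,SIG_DOWN
SD2,120,SIG_DOWN
SD2,60,SIG_DOWN
SD2,30,SIG_DOWN
ApEn,300,SIG_DOWN
ApEn,180,SIG_DOWN
ApEn,120,NA
ApEn,60,NA
ApEn,30,NA
SampEn,300,SIG_DOWN
SampEn,180,SIG_DOWN
SampEn,120,SIG_DOWN
SampEn,60,SIG_DOWN
SampEn,30,NA
D2,300,SIG_DOWN
D2,180,SIG_DOWN
D2,120,SIG_DOWN
D2,60,SIG_DOWN
D2,30,NA
dfa1,300,SIG_DOWN
dfa1,180,SIG_DOWN
dfa1,120,SIG_DOWN
dfa1,60,SIG_DOWN
dfa1,30,NA
dfa2,300,NS_UP
dfa2,180,NS_UP
dfa2,120,NS_UP
dfa2,60,NS_DOWN
dfa2,30,NA
RPlmean,300,SIG_UP
RPlmean,180,SIG_UP
RPlmean,120,SIG_UP
RPlmean,60,NS_UP
RPlmean,30,NA
RPlmax,300,NS_DOWN
RPlmax,180,SIG_DOWN
RPlmax,120,NS_DOWN
RPlmax,60,NS_UP
RPlmax,30,NA
REC,300,SIG_UP
REC,180,SIG_UP
REC,120,SIG_UP
REC,60,NS_UP
REC,30,NA
RPadet,300,SIG_UP
RPadet,180,NS_UP
RPadet,120,NS_UP
RPadet,60,NS_DOWN
RPadet,30,NA
ShanEn,300,SIG_UP
ShanEn,180,SIG_UP
ShanEn,120,SIG_UP
ShanEn,60,SIG_UP
ShanEn,30,NA
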