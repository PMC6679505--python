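# Reference aggregated confusion matrix: INCART protocol, 7 classes,
# dual-lead (II + V5) cascade, 5-fold aggregate, 1720 beats.
true\pred,N,V,A,F,n,R,j
N,487,2,0,5,4,0,2
V,4,484,0,11,0,1,0
A,22,2,176,0,0,0,0
F,17,16,1,166,0,0,0
n,8,0,0,0,22,0,0
R,1,2,0,0,0,197,0
j,4,0,0,0,0,0,86
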