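# Reference aggregated confusion matrix: INCART protocol, 7 classes,
# dual-lead (II + V1) cascade, 5-fold aggregate, 1720 beats.
true\pred,N,V,A,F,n,R,j
N,484,1,1,8,4,0,2
V,0,492,0,8,0,0,0
A,26,1,173,0,0,0,0
F,24,17,0,159,0,0,0
n,6,0,0,0,24,0,0
R,0,1,0,0,0,199,0
j,3,1,0,0,0,0,86
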