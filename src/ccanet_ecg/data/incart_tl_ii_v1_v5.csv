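# Reference aggregated confusion matrix: INCART protocol, 7 classes,
# three-lead (II + V1 + V5) cascade, 5-fold aggregate, 1720 beats.
true\pred,N,V,A,F,n,R,j
N,489,2,1,2,4,0,2
V,0,490,0,10,0,0,0
A,16,3,179,2,0,0,0
F,14,9,1,176,0,0,0
n,6,0,0,0,24,0,0
R,0,2,0,0,0,198,0
j,1,1,0,1,0,0,87
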