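# Reference aggregated confusion matrix: INCART protocol, 7 classes,
# dual-lead (V1 + V5) cascade, 5-fold aggregate, 1720 beats.
true\pred,N,V,A,F,n,R,j
N,487,2,0,5,4,0,2
V,3,485,0,10,0,2,0
A,20,2,174,4,0,0,0
F,25,14,1,160,0,0,0
n,7,0,0,0,23,0,0
R,0,2,0,0,0,198,0
j,2,0,0,0,0,0,88
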