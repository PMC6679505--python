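# Reference aggregated confusion matrix: MIT-BIH protocol, 15 classes,
# dual-lead (II + V5) cascade, 10-fold aggregate, 3350 beats.
# One ambiguous count (A->N) restored so the A row matches its class
# inventory of 200 beats.
true\pred,r,N,A,V,P,x,F,j,L,a,J,R,!,E,f
r,190,3,3,1,0,0,0,0,3,0,0,0,0,0,0
N,2,973,1,2,0,0,0,19,3,0,0,0,0,0,0
A,0,22,154,0,0,0,0,16,0,1,7,0,0,0,0
V,1,8,0,184,0,1,2,0,1,1,0,0,2,0,0
P,0,0,0,0,200,0,0,0,0,0,0,0,0,0,0
x,1,0,0,0,0,98,0,0,0,0,0,0,0,1,0
F,3,12,1,7,0,0,177,0,0,0,0,0,0,0,0
j,0,7,0,0,0,0,0,193,0,0,0,0,0,0,0
L,0,0,0,1,0,0,0,0,199,0,0,0,0,0,0
a,1,7,1,3,0,0,1,0,0,87,0,0,0,0,0
J,0,0,5,1,0,0,0,0,0,0,194,0,0,0,0
R,0,1,0,0,0,0,0,1,0,0,0,48,0,0,0
!,0,0,0,2,0,0,0,0,0,0,0,0,198,0,0
E,0,1,0,2,0,0,0,0,0,0,0,0,1,96,0
f,0,0,0,0,0,0,0,0,0,0,0,0,0,0,200
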