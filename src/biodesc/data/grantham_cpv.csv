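residue,composition,polarity,volume
A,0.0,8.1,31
C,2.75,5.5,55
D,1.38,13.0,54
E,0.92,12.3,83
F,0.0,5.2,132
G,0.74,9.0,3
H,0.58,10.4,96
I,0.0,5.2,111
K,0.33,11.3,119
L,0.0,4.9,111
M,0.0,5.7,105
N,1.33,11.6,56
P,0.39,8.0,32.5
Q,0.89,10.5,85
R,0.65,10.5,124
S,1.42,9.2,32
T,0.71,8.6,61
V,0.0,5.9,84
W,0.13,5.4,170
Y,0.2,6.2,136
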