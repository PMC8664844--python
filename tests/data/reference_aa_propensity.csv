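residue,propensity,pct_positive,pct_negative,pct_difference
E,510.18,9.28,6.49,2.79
K,480.00,7.83,5.79,2.04
V,470.75,8.45,7.09,1.36
R,464.08,6.47,5.14,1.32
I,435.65,7.41,6.45,0.96
G,433.48,7.34,7.12,0.22
Y,425.93,3.42,2.89,0.53
P,421.40,4.26,4.13,0.13
C,388.28,0.92,1.07,-0.15
M,387.10,2.33,2.50,-0.17
D,386.25,5.18,5.34,-0.17
W,383.25,0.88,1.09,-0.22
L,367.18,9.35,10.14,-0.79
H,364.58,1.65,2.22,-0.57
S,363.20,4.85,5.90,-1.05
F,351.25,3.63,4.06,-0.43
N,332.48,3.33,4.14,-0.80
A,323.63,7.29,8.90,-1.61
T,306.00,4.13,5.32,-1.20
Q,255.43,2.01,4.21,-2.20
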