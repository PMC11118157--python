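patient_id,age,sex,pso,psa,comorbidities
A,52,M,true,false,
B,43,M,true,true,Alcoholic hepatitis;TAILS
C,44,M,true,false,
D,59,M,true,true,
E,51,M,true,true,
F,55,F,true,true,
G,44,M,true,true,
H,65,F,true,true,
I,57,F,true,true,TAILS
J,40,M,true,false,
K,54,M,true,false,HBV
L,42,M,true,false,
M,65,F,true,false,Tb
N,54,M,true,true,
O,39,M,true,true,Kikuchi-Fujimoto disease;MI
P,43,M,true,false,HTN;CKD
Q,32,M,true,true,
R,42,M,true,false,
S,43,M,true,false,Hyperlipidemia
T,43,M,true,false,
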