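patient_id,biologic,order_index,pasi_before,pasi_after,months_to_outcome,tested_before_start
A,ada,2,3.2,2.6,6,false
A,ust,1,3.2,0,10,false
B,ada,1,15,16,6,false
B,ust,2,15,0.2,6,false
C,ada,2,13,0.5,6,false
C,ust,1,13,12,6,false
D,ada,1,7.5,15,12,false
D,ust,2,7.5,0.8,6,true
E,ada,1,25,12,26,false
E,gus,2,8,4.3,6,false
E,sec,3,8,1.2,6,true
F,ada,2,4.1,0.8,6,true
F,gol,1,4.1,0.4,29,false
G,ixe,3,31.2,0,6,true
G,ust,1,56.5,22.4,54,false
G,sec,2,22.4,2.4,20,false
H,ust,2,11.4,3.5,24,false
H,ada,1,15.5,11.4,52,false
H,sec,3,15.3,1,15,false
I,ada,1,3.8,2,47,false
I,sec,2,2,0,6,false
J,ixe,2,15,1.2,6,false
J,ust,1,16,0,24,false
K,ust,1,15,3.7,24,false
K,ixe,2,11.7,0,6,false
L,ust,1,36.8,4,24,false
L,ixe,2,16,1,6,false
M,ada,1,20,5.2,27,false
M,sec,2,16,0.9,18,false
N,ust,1,27,3.1,24,false
N,gol,2,27,9.1,19,false
N,ixe,3,27,0,10,false
O,ust,3,19.2,3,30,false
O,sec,2,19.2,9.8,6,false
P,ixe,1,13.1,0,6,false
P,gus,2,13.1,0,20,false
Q,ust,1,16,1.2,24,false
Q,gus,2,27,0,33,false
R,ust,1,26,0,24,false
R,ris,2,16.4,0,21,false
S,ust,1,7.8,4.5,24,false
S,ixe,2,8.5,0,12,false
T,ust,1,18.4,3.6,12,false
T,ris,2,18.4,1.2,12,false
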