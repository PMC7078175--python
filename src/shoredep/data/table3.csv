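segment,day1,day2,day3,day4
A,0,1,1,0
B,0,1,1,0
C,0,1,1,0
D,0,1,1,0
E,0,1,2,0
F,0,1,1,0
G,0,0,2,1
H,0,0,1,2
I,1,1,0,0
J,0,2,1,0
K,4,4,0,0
L,0,0,13,13
M,0,1,5,0
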