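n,beach_persistence,marsh_persistence
E,0.86,0.43
0,1.00,1.00
1,0.72,0.46
2,0.61,0.31
3,0.54,0.24
4,0.49,0.20
5,0.45,0.18
6,0.43,0.16
7,0.41,0.15
8,0.39,0.14
9,0.37,0.13
10,0.36,0.13
11,0.35,0.12
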