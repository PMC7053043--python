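,A,B,C,D
A,143,8,0,0
B,14,30,1,0
C,0,5,68,3
D,0,0,3,16
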