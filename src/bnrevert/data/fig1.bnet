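targets, factors
A, I | B
B, I
C, A & D
D, B
E, A
O, (E | C) & C
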