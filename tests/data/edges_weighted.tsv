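# ten-edge weighted fixture; exactly one edge falls below weight 0.5
A	B	0.9
A	C	0.8
B	C	0.7
C	D	0.6
D	E	0.1
D	F	0.95
E	F	0.85
F	G	0.75
G	H	0.65
H	A	0.55
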