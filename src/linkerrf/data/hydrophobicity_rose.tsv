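# Rose hydrophobicity scale: mean fractional area buried in globular proteins.
aa	rose
A	0.74
R	0.64
N	0.63
D	0.62
C	0.91
Q	0.62
E	0.62
G	0.72
H	0.78
I	0.88
L	0.85
K	0.52
M	0.85
F	0.88
P	0.64
S	0.66
T	0.70
W	0.85
Y	0.76
V	0.86
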