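# SARAH1 scale: unique signed five-bit code per amino acid, exactly two
# non-zero entries; codes rank residues by Rose hydrophobicity, the 10 most
# hydrophobic positive, the 10 least hydrophobic the negative mirror image.
aa	b1	b2	b3	b4	b5
C	1	1	0	0	0
F	1	0	1	0	0
I	1	0	0	1	0
V	1	0	0	0	1
L	0	1	1	0	0
W	0	1	0	1	0
M	0	1	0	0	1
H	0	0	1	1	0
Y	0	0	1	0	1
A	0	0	0	1	1
G	0	0	0	-1	-1
T	0	0	-1	0	-1
S	0	0	-1	-1	0
R	0	-1	0	0	-1
P	0	-1	0	-1	0
N	0	-1	-1	0	0
D	-1	0	0	0	-1
Q	-1	0	0	-1	0
E	-1	0	-1	0	0
K	-1	-1	0	0	0
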