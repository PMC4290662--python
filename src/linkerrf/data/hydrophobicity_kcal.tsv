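# Side-chain hydrophobicity (kcal/mol, cyclohexane-to-water transfer, pH 7),
# non-polar (positive) to polar (negative).
# NOTE: the K value is stored exactly as published (5.55). Given K's position
# between Q and N in the polar tail of the published ranking, the sign is
# probably a typo for -5.55; we keep the printed value and do not silently
# correct it.
aa	kcal_per_mol
I	4.92
L	4.92
V	4.04
P	4.04
F	2.98
M	2.35
W	2.33
A	1.81
C	1.28
G	0.94
Y	-0.14
T	-2.57
S	-3.40
H	-4.66
Q	-5.54
K	5.55
N	-6.64
E	-6.81
D	-8.72
R	-14.92
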