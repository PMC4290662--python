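# Amino-acid composition (percent) in inter-domain linker and in domain
# segments of the Swiss-Prot-derived linker benchmark, with the linker
# propensity index S_i = -ln(f_linker / f_domain).
# Negative S_i: residue over-represented in linkers.
aa	linker_pct	domain_pct	linker_index
P	7.95	4.93	-0.478
S	8.32	6.97	-0.177
T	6.68	5.67	-0.163
E	7.53	6.62	-0.128
K	6.30	5.64	-0.112
Q	4.35	4.04	-0.073
A	7.03	6.64	-0.058
V	7.33	6.96	-0.052
R	5.39	5.39	0.000
D	5.39	5.47	0.016
N	4.29	4.41	0.027
I	4.86	5.16	0.060
L	7.62	8.75	0.138
H	2.13	2.59	0.195
F	2.92	3.71	0.240
M	1.47	1.94	0.275
Y	2.49	3.44	0.322
G	5.46	7.60	0.331
C	1.62	2.53	0.447
W	0.89	1.56	0.564
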