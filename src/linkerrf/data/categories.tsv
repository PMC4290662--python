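# Categorical physiochemical classification of the 20 standard amino acids:
# side-chain charge, side-chain polarity, aromaticity, size, and electronic
# (electron donor/acceptor) property.
aa	charge	polarity	aromaticity	size	electronic
A	neutral	nonpolar	neutral	small	strong_donor
C	neutral	polar	neutral	large	neutral
D	negative	polar	neutral	medium	strong_donor
E	negative	polar	neutral	large	strong_donor
F	neutral	nonpolar	aromatic	large	weak_acceptor
G	neutral	nonpolar	neutral	small	neutral
H	positive	polar	aromatic	large	neutral
I	neutral	nonpolar	aliphatic	large	weak_donor
K	positive	polar	neutral	large	strong_acceptor
L	neutral	nonpolar	aliphatic	large	weak_donor
M	neutral	nonpolar	neutral	large	weak_acceptor
N	neutral	polar	neutral	medium	strong_acceptor
P	neutral	nonpolar	neutral	small	strong_donor
Q	neutral	polar	neutral	large	weak_acceptor
R	positive	polar	neutral	large	strong_acceptor
S	neutral	polar	neutral	small	neutral
T	neutral	polar	neutral	medium	weak_acceptor
V	neutral	nonpolar	aliphatic	large	weak_donor
W	neutral	nonpolar	aromatic	large	neutral
Y	neutral	polar	aromatic	large	weak_acceptor
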