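# Amino-acid background frequencies of Robinson & Robinson (1991),
# PNAS 88:8880-8884, as used by BLAST for composition statistics.
# Used as the default backgrounds p(a) when transforming a log-odds
# substitution matrix back to joint substitution probabilities.
# aa	frequency
A	0.07805
C	0.01925
D	0.05364
E	0.06295
F	0.03856
G	0.07377
H	0.02199
I	0.05142
K	0.05744
L	0.09019
M	0.02243
N	0.04487
P	0.05203
Q	0.04264
R	0.05129
S	0.07120
T	0.05841
V	0.06441
W	0.01330
Y	0.03216
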