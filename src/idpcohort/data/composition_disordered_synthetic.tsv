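# Synthetic stand-in reference composition (constructed, not a
# published table): ordered globular-like residue frequencies for the
# fractional-difference composition profile.
W	0.005652
F	0.022282
Y	0.019206
I	0.038428
M	0.016665
L	0.072024
V	0.055778
N	0.036307
C	0.014135
T	0.051507
A	0.077726
G	0.072579
R	0.057989
D	0.068448
H	0.027249
Q	0.049141
S	0.074775
K	0.080352
E	0.091730
P	0.068027
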