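# Synthetic stand-in reference composition (constructed, not a
# published table): ordered globular-like residue frequencies for the
# fractional-difference composition profile.
W	0.015372
F	0.053665
Y	0.041273
I	0.074142
M	0.029018
L	0.113663
V	0.080066
N	0.047544
C	0.016927
T	0.056526
A	0.078294
G	0.067191
R	0.049386
D	0.053660
H	0.019671
Q	0.032670
S	0.045772
K	0.045266
E	0.047521
P	0.032372
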