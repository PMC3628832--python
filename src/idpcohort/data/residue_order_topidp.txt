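# Display order for composition profiles: the 20 standard residues ranked by
# increasing disorder-promoting potential (TopIDP scale), order-promoting on
# the left through disorder-promoting on the right.
W F Y I M L V N C T A G R D H Q S K E P
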