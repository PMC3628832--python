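# Amino-acid propensity scales used by the per-residue profilers.
# kyte_doolittle: raw hydropathy (higher = more hydrophobic = order-promoting);
#   min-max normalized to [0,1] via (v + 4.5)/9 where the CH boundary needs it.
# topidp: order-disorder propensity scale (higher = more disorder-promoting),
#   signed, natural threshold at 0.
kyte_doolittle:
  higher_means: order
  declared_range: [-4.5, 4.5]
  values:
    A: 1.8
    R: -4.5
    N: -3.5
    D: -3.5
    C: 2.5
    Q: -3.5
    E: -3.5
    G: -0.4
    H: -3.2
    I: 4.5
    L: 3.8
    K: -3.9
    M: 1.9
    F: 2.8
    P: -1.6
    S: -0.8
    T: -0.7
    W: -0.9
    Y: -1.3
    V: 4.2
topidp:
  higher_means: disorder
  declared_range: [-0.884, 0.987]
  values:
    A: 0.06
    R: 0.18
    N: 0.007
    D: 0.192
    C: 0.02
    Q: 0.318
    E: 0.736
    G: 0.166
    H: 0.303
    I: -0.486
    L: -0.326
    K: 0.586
    M: -0.397
    F: -0.697
    P: 0.987
    S: 0.341
    T: 0.059
    W: -0.884
    Y: -0.51
    V: -0.121
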