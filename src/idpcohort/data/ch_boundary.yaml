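# Charge-hydropathy boundary line |<R>| = slope * <H> - intercept separating
# natively unfolded (above) from compact (below) proteins, with <H> the mean
# Kyte-Doolittle hydropathy min-max normalized to [0,1] and <R> the mean net
# charge per residue (D,E = -1; K,R = +1; all others 0).
slope: 2.785
intercept: 1.151
hydropathy_scale: kyte_doolittle
hydropathy_normalization: [-4.5, 4.5]
charge:
  negative: [D, E]
  positive: [K, R]
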