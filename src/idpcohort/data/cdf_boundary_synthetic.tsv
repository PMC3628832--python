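# Synthetic default CDF order/disorder boundary: a constructed monotone
# boundary in the style of the published PONDR CDF boundaries (threshold,
# boundary fraction of residues at or below that disorder score). Replace
# with a predictor-matched boundary file for exact reproduction of any
# published classification.
0.2	0.23
0.3	0.32
0.4	0.41
0.5	0.50
0.6	0.59
0.7	0.68
0.8	0.77
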