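cell_type	parent	marker	relation	valley_index
B	None	CD19	above_valley	1
B	None	CD3	below_valley	1
T	None	CD3	above_valley	1
T	None	CD19	below_valley	1
CD4 T	T	CD4	above_valley	1
CD4 T	T	CD8	below_valley	1
CD8 T	T	CD8	above_valley	1
CD8 T	T	CD4	below_valley	1
NK	None	CD3	below_valley	1
NK	None	CD56	above_valley	1
Monocyte	None	CD14	above_valley	1
Monocyte	None	CD3	below_valley	1
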