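# Published large-scale tally of residues by burial state (RSA <= 0.15
# buried / > 0.15 exposed) and DSSP 8-state category, over ~6.03 million
# residues.  Used by examples and the reproduction script as a reference
# input for the association analysis.
bin	H	G	I	E	B	T	S	L
buried	1000536	82456	643	813132	29114	198608	180445	479341
exposed	999976	141550	391	466328	32103	446346	293307	865191
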