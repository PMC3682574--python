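# PRM consensus patterns; f = hydrophobic residue class, x = any residue
PRM1	PPfPfffQffP
PRM2	QffPfPQPfffGP
PRM3	ffPPPfPfff
PRM4	GfxxffPffPfP
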