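accession_a	accession_b	n_mismatch	round
PB.1.1	GENA-201	0	0
PB.2.1	GENB-201	0	0
PB.2.2	GENB-202	0	0
PB.3.1	GENC-201	0	0
PB.3.2	GENC-203	0	0
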