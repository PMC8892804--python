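gene_id	category	n_sample	n_reference	n_shared	n_novel
GENA	PartialOverlap	3	2	1	2
GENB	PartialOverlap	3	3	2	1
GENC	PartialOverlap	3	3	2	1
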