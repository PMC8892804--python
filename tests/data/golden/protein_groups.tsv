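members	n_peptides	status	resolution	fractions
PB.1.4	82	retained	unresolved	PB.1.4:1.0000
PB.3.1	80	retained	unresolved	PB.3.1:1.0000
PB.2.1|PB.2.2	61	retained	resolved_to:PB.2.1	PB.2.1:0.9500;PB.2.2:0.0500
PB.1.1	67	retained	unresolved	PB.1.1:1.0000
PB.2.3	34	rescued_case1	unresolved	PB.2.3:1.0000
PB.3.2	79	rescued_case1	unresolved	PB.3.2:1.0000
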