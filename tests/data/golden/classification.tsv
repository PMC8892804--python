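accession	transcript_class	protein_class	subclass	novel_elements
PB.1.1	FSM	pFSM	reference-match	
PB.1.2	ISM	pFSM	reference-match	
PB.1.3	NNC	pNNC	novel-junction	novel-junction:1519-1994
PB.1.4	NIC	pNIC	known-combination	
PB.1.5	FSM	other	no-called-orf	
PB.2.1	FSM	pFSM	reference-match	
PB.2.2	FSM	pFSM	reference-match	
PB.2.3	ISM	pNIC	known-combination	
PB.2.4	ISM	pISM	5prime-degradation	novel-n-terminus
PB.2.5	NIC	other	no-called-orf	
PB.3.1	FSM	pFSM	reference-match	
PB.3.2	FSM	pFSM	reference-match	
PB.3.3	NNC	pNNC	novel-junction	novel-junction:1546-2033
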