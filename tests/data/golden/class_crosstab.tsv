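transcript_class	other	pFSM	pISM	pNIC	pNNC
FSM	1	5	0	0	0
ISM	0	1	1	1	0
NIC	1	0	0	1	0
NNC	0	0	0	0	2
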