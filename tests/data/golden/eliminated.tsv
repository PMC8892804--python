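accession	case
PB.1.3	case1
PB.2.3	case1
PB.3.2	case1
PB.3.3	case1
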