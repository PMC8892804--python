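sequence
APAFLLAGFSCWLVVR
APAFLLAGFSCWLVVRFCFWVVSVSSFVPVR
APAFLLAGFSCWLVVRFCFWVVSVSSFVPVRFLCGVAGVWWR
ARFRGGLAPPLPFLWLCFLLAR
CPVVPFGVCCCPRLRAPAFLLAGFSCWLVVR
FCFWVVSVSSFVPVR
FCFWVVSVSSFVPVRFLCGVAGVWWR
FCFWVVSVSSFVPVRFLCGVAGVWWRSR
FLCGVAGVWWR
FLCGVAGVWWRSR
FLCGVAGVWWRSRAR
FRGGLAPPLPFLWLCFLLAR
FRGGLAPPLPFLWLCFLLARGGAPFCAGACSLAALGCVAAGCR
LRAPAFLLAGFSCWLVVR
LRAPAFLLAGFSCWLVVRFCFWVVSVSSFVPVR
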