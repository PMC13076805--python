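enzyme_name	cleave_after	blocked_before
trypsin	KR	P
gluc	E
gluc_de	ED
chymotrypsin	FYWLM
chymotrypsin_strict	FYW	P
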