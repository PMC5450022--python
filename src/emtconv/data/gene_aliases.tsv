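alias	official
SNAI2	SLUG
TWIST	TWIST1
B2ME	B2M
KRT-18	KRT18
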