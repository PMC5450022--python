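EMT_UP	synthetic stand-in up-signature	VIM	CDH2	FN1	ZEB1	ZEB2	SNAI1	SLUG	TWIST1	MMP2	MMP9	COL1A1	COL3A1	SPARC	TNC	ITGB1
EMT_DOWN	synthetic stand-in down-signature	CDH1	EPCAM	OCLN	CLDN3	CLDN4	CLDN7	DSP	KRT8	KRT18	KRT19	TJP1	ESRP1	ESRP2	GRHL2	MUC1
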