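KEGG00190_OXIDATIVE_PHOSPHORYLATION	representative member subset (synthetic fixture)	NDUFA1	NDUFA2	NDUFB5	NDUFS1	NDUFV1	SDHA	SDHB	SDHC	UQCRC1	UQCRC2	UQCRFS1	CYC1	COX4I1	COX5A	COX6B1	COX7A2	ATP5F1A	ATP5F1B	ATP5F1C	ATP5PB
KEGG00010_GLYCOLYSIS	representative member subset (synthetic fixture)	HK1	HK2	GPI	PFKL	PFKM	PFKP	ALDOA	ALDOC	TPI1	GAPDH	PGK1	PGAM1	ENO1	ENO2	PKM	LDHA	LDHB	PDHA1
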