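human	mouse
VIM	Vim
CDH2	Cdh2
FN1	Fn1
ZEB1	Zeb1
ZEB2	Zeb2
SNAI1	Snai1
SLUG	Slug
TWIST1	Twist1
MMP2	Mmp2
MMP9	Mmp9
COL1A1	Col1a1
COL3A1	Col3a1
SPARC	Sparc
TNC	Tnc
ITGB1	Itgb1
CDH1	Cdh1
EPCAM	Epcam
OCLN	Ocln
CLDN3	Cldn3
CLDN4	Cldn4
CLDN7	Cldn7
DSP	Dsp
KRT8	Krt8
KRT18	Krt18
KRT19	Krt19
TJP1	Tjp1
ESRP1	Esrp1
ESRP2	Esrp2
GRHL2	Grhl2
MUC1	Muc1
NDUFA1	Ndufa1
NDUFA2	Ndufa2
NDUFB5	Ndufb5
NDUFS1	Ndufs1
NDUFV1	Ndufv1
SDHA	Sdha
SDHB	Sdhb
SDHC	Sdhc
UQCRC1	Uqcrc1
UQCRC2	Uqcrc2
UQCRFS1	Uqcrfs1
CYC1	Cyc1
COX4I1	Cox4i1
COX5A	Cox5a
COX6B1	Cox6b1
COX7A2	Cox7a2
ATP5F1A	Atp5f1a
ATP5F1B	Atp5f1b
ATP5F1C	Atp5f1c
ATP5PB	Atp5pb
HK1	Hk1
HK2	Hk2
GPI	Gpi
PFKL	Pfkl
PFKM	Pfkm
PFKP	Pfkp
ALDOA	Aldoa
ALDOC	Aldoc
TPI1	Tpi1
GAPDH	Gapdh
PGK1	Pgk1
PGAM1	Pgam1
ENO1	Eno1
ENO2	Eno2
PKM	Pkm
LDHA	Ldha
LDHB	Ldhb
PDHA1	Pdha1
STAT3	Stat3
SOX2	Sox2
MAP1B	Map1b
RELN	Reln
ROBO1	Robo1
TUBB3	Tubb3
ACTB	Actb
B2M	B2m
HPRT1	Hprt1
TBP	Tbp
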