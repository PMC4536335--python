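SETD6	UBQLN1	HDAC3	LOC653441
RNF207	NDOR1	CLTCL1	PHC1
ABCC8	IGHM	PPIL4	MATR3
DNASE1L1	FBXO4	REST	CLYBL
ACD	PRKAA1	LPHN3	MLLT4
NUP155	RIPK4	DKFZp667	EFCBP2
FAM91A2	TASP1	ACTN2	KIAA0528
FAM91A1	ADRBK2	OSBPL6	PPM1J
MGC5566	FAM46C	STAR	TMEFF1
MRPL30	ITIH4	FUNDC2	SGK269
MAGIX	C1orf164	RAB15	LOC389634
HFE	IL17RD	EDA
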