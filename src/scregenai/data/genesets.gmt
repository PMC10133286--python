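cell_cycle_G1S	editable default: G1-to-S transition	CCNE1	CCNE2	CDC6	CDC45	MCM2	MCM3	MCM4	MCM5	MCM6	MCM7	PCNA	E2F1	GINS2	SLBP	RRM1
cell_cycle_S	editable default: DNA synthesis	RRM2	TYMS	FEN1	DHFR	POLA1	RFC4	RAD51	BRCA1	EXO1	CLSPN	CDC25A	UNG	MSH2
cell_cycle_G2M	editable default: G2-to-mitosis transition	CCNB1	CCNB2	CDK1	CDC20	PLK1	TOP2A	BUB1	BUB1B	CCNA2	CDC25C	CENPA	NDC80	MKI67
cell_cycle_M	editable default: mitosis	AURKA	AURKB	KIF2C	KIF20A	CENPE	CENPF	TPX2	BIRC5	INCENP	CDCA8	SPAG5
cell_cycle_cytokinesis	editable default: cytokinesis	ALKBH4	ANLN	AURKB	CNTROB	KLHDC8B	RACGAP1	ECT2	KIF23	PRC1	CIT
pathway_MAPK	editable default: MAPK signalling	MAPK1	MAPK3	MAP2K1	MAP2K2	RAF1	BRAF	KRAS	HRAS	NRAS	DUSP1	FOS	JUN	ELK1	EGFR
pathway_HIPPO	editable default: HIPPO/YAP signalling	YAP1	WWTR1	TEAD1	TEAD2	TEAD3	TEAD4	LATS1	LATS2	STK3	STK4	SAV1	MOB1A	MOB1B	NF2
pathway_cAMP	editable default: cAMP signalling	PRKACA	PRKACB	PRKAR1A	PRKAR2A	ADCY1	ADCY5	ADCY6	CREB1	PDE4A	PDE4B	GNAS	PKIA
pathway_JAK_STAT	editable default: JAK-STAT signalling	JAK1	JAK2	JAK3	TYK2	STAT1	STAT2	STAT3	STAT4	STAT5A	STAT5B	STAT6	SOCS1	SOCS3	IL6R
pathway_RAS	editable default: RAS signalling	KRAS	HRAS	NRAS	RASA1	RASGRF1	RASGRP1	SOS1	SOS2	RALA	RALB	RAPGEF1	RIN1
pathway_TGFb	editable default: TGF-beta signalling	TGFB1	TGFB2	TGFB3	TGFBR1	TGFBR2	SMAD2	SMAD3	SMAD4	SMAD7	ACVR1	BMP4	INHBA
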