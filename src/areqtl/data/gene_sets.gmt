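ARE_GENES	37 human genes with NRF2/ARE binding sites (curated fixture)	AKR1C1	AKR1C2	AKR1C3	ALDH3A1	CBR1	FTH1	FTL	GCLM	GCLC	GPX2	NQO1	PIR	PRDX1	PSMA3	SAT1	SLC7A11	SOD1	SQSTM1	TALDO1	TKT	TXN	TXNRD1	UGT1A6	EPHX1	HMOX1	GSTP1	GSTM3	GSTA4	ME1	G6PD	PGD	IDH1	CAT	GSR	ABCC1	SRXN1	NQO2
HISTIDINE_METABOLISM	control pathway set (fixture)	HAL	HDC	FTCD	AMDHD1	UROC1	ASPA	CNDP1	CARNS1	ALDH1B1	MAOA	ABP1	METTL6
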