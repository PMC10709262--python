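G1.S	indicative G1/S-peaking genes, v1 (for real-data use; not load-bearing in tests)	CCNE1	CCNE2	E2F1	CDC6	PCNA	MCM2	MCM6	CDT1	SLBP	GINS2	CDC25A	DHFR
S	indicative S-peaking genes, v1	RRM2	CDC45	MCM4	RFC4	RRM1	TYMS	GINS1	CLSPN	EXO1	FEN1	POLA1	UNG
G2	indicative G2-peaking genes, v1	CCNA2	TOP2A	CCNF	CKS1B	NDC80	CENPA	KIF11	MELK	SMC4	NUSAP1	UBE2C	TACC3
G2.M	indicative G2/M-peaking genes, v1	CCNB1	CCNB2	CDC20	PLK1	AURKA	BUB1	CENPF	CDC25C	TPX2	KIF23	AURKB	CDK1
M.G1	indicative M/G1-peaking genes, v1	CDKN3	KPNA2	PTTG1	RAD21	ANLN	CKAP2	HMGB2	PSRC1	TROAP	GTSE1	CTCF	LBR
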