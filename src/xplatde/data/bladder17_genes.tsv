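gene_id	symbol
70	ACTC1
652	BMP4
991	CDC20
1421	CRYGD
1621	DBH
2705	GJB1
3052	HCCS
3889	KRT83
3973	LHCGR
4239	MFAP4
4359	MPZ
4807	NHLH1
6870	TACR3
6876	TAGLN
7169	TPM2
8404	SPARCL1
10548	TM9SF1
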