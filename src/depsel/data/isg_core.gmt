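ISG_CORE	interferon-stimulated gene core signature (38 genes)	ADAR	BST2	CASP1	CMPK2	CXCL10	DDX60	DHX58	EIF2AK2	EPSTI1	GBP4	HERC6	IFI35	IFIH1	IFIT2	IFIT3	IRF7	ISG15	ISG20	MX1	NMI	OASL	OGFR	PARP12	PARP14	PNPT1	PSME2	RSAD2	RTP4	SAMD9L	SP110	STAT2	TDRD7	TRAFD1	TRIM14	TRIM21	TRIM25	UBE2L6	USP18
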