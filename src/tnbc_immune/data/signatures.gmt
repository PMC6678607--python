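CD8_T_ACTIVATED	effector CD8 T-cell activation program (editable default)	CD8A	CD8B	GZMA	GZMB	GZMH	GZMK	GZMM	PRF1	IFNG	NKG7	KLRD1	CD3D	CD3E	CD3G	CD2	LCK	ZAP70	TBX21	EOMES	CST7	CTSW	APOBEC3G
ESTIMATE_IMMUNE	immune-infiltrate marker genes (editable default)	PTPRC	CD53	LAPTM5	SRGN	CD2	CD3E	CD48	CD52	IL7R	CCL5	CD37	CXCR4	LTB	CORO1A	CD27	ITGAL	LCP2	SLA	ARHGAP15	EVI2B
ESTIMATE_STROMAL	stromal/fibroblast marker genes (editable default)	COL1A1	COL1A2	COL3A1	COL5A1	COL5A2	COL6A3	FAP	DCN	FBLN1	THBS2	POSTN	SPARC	LUM	MMP2	PDGFRB	FN1	VCAN	AEBP1	SULF1	CTSK
TREG_SUPPRESSIVE	regulatory T-cell program (editable default)	FOXP3	IL2RA	CCR8	IKZF2	TNFRSF18	CTLA4	ENTPD1	IL10	TGFB1	LAG3
NK_CELLS	natural-killer-cell program (editable default)	NCR1	NCR3	KLRB1	KLRC1	KLRD1	KIR2DL3	GNLY	XCL1	XCL2	PRF1
B_MEMORY	memory B-cell program (editable default)	CD19	MS4A1	CD27	CD79A	CD79B	TNFRSF13B	AIM2	BANK1	BLK	CD40
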