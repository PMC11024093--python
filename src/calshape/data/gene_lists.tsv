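list	gene
epithelial	CDH1
epithelial	CLDN3
epithelial	CLDN4
epithelial	CLDN7
epithelial	CRB3
epithelial	DSP
epithelial	EHF
epithelial	EpCAM
epithelial	EPN3
epithelial	GRHL2
epithelial	IRF6
epithelial	KRT5
epithelial	KRT5
epithelial	KRT8
epithelial	KRT14
epithelial	KRT18
epithelial	KRT19
epithelial	LLGL2
epithelial	MARVELD3
epithelial	MYO5B
epithelial	OVOL1
epithelial	PRSS8
epithelial	RAB25
epithelial	S100A14
epithelial	ST14
epithelial	TJP3
mesenchymal	AP1M1
mesenchymal	BICD2
mesenchymal	CCDC88A
mesenchymal	CDH2
mesenchymal	CMTM3
mesenchymal	EMP3
mesenchymal	FN1
mesenchymal	GNB4
mesenchymal	QKI
mesenchymal	SERPINE1
mesenchymal	SNAI1
mesenchymal	SNAI2
mesenchymal	VIM
mesenchymal	ZEB1
mesenchymal	ZEB2
subtype_marker	AR
subtype_marker	AURKA
subtype_marker	EGFR
subtype_marker	ERBB2
subtype_marker	ESR1
subtype_marker	FOXA1
subtype_marker	FOXM1
subtype_marker	MKI67
subtype_marker	PGR
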