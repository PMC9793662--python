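cell_type	gene_symbol	species
T cells	CD3D	human
T cells	CD3E	human
T cells	CD3G	human
T cells	CD2	human
T cells	CD7	human
T cells	IL7R	human
T cells	LCK	human
T cells	TRAC	human
B cells	CD19	human
B cells	MS4A1	human
B cells	CD79A	human
B cells	CD79B	human
B cells	IGHM	human
B cells	PAX5	human
B cells	EBF1	human
B cells	BANK1	human
NK cells	NKG7	human
NK cells	GNLY	human
NK cells	KLRD1	human
NK cells	NCR1	human
NK cells	PRF1	human
NK cells	KLRF1	human
NK cells	EOMES	human
NK cells	FCGR3A	human
Monocytes	CD14	human
Monocytes	LYZ	human
Monocytes	S100A8	human
Monocytes	S100A9	human
Monocytes	FCN1	human
Monocytes	VCAN	human
Monocytes	CTSS	human
Monocytes	CEBPD	human
Dendritic cells	FCER1A	human
Dendritic cells	CD1C	human
Dendritic cells	CLEC9A	human
Dendritic cells	ITGAX	human
Dendritic cells	IRF8	human
Dendritic cells	FLT3	human
Dendritic cells	CLEC10A	human
Dendritic cells	BATF3	human
Macrophages	CD68	human
Macrophages	CD163	human
Macrophages	MRC1	human
Macrophages	MSR1	human
Macrophages	MARCO	human
Macrophages	MERTK	human
Macrophages	C1QA	human
Macrophages	C1QB	human
Neutrophils	ELANE	human
Neutrophils	MPO	human
Neutrophils	PRTN3	human
Neutrophils	FCGR3B	human
Neutrophils	CSF3R	human
Neutrophils	CXCR2	human
Neutrophils	LCN2	human
Neutrophils	CAMP	human
Cardiomyocytes	TNNT2	human
Cardiomyocytes	MYH6	human
Cardiomyocytes	MYL2	human
Cardiomyocytes	NPPA	human
Cardiomyocytes	ACTC1	human
Cardiomyocytes	TNNI3	human
Cardiomyocytes	MYBPC3	human
Cardiomyocytes	NKX2-5	human
Fibroblasts	COL1A1	human
Fibroblasts	COL1A2	human
Fibroblasts	COL3A1	human
Fibroblasts	PDGFRA	human
Fibroblasts	DCN	human
Fibroblasts	LUM	human
Fibroblasts	FBLN1	human
Fibroblasts	THY1	human
Endothelial cells	PECAM1	human
Endothelial cells	VWF	human
Endothelial cells	CDH5	human
Endothelial cells	KDR	human
Endothelial cells	CLDN5	human
Endothelial cells	TEK	human
Endothelial cells	ESAM	human
Endothelial cells	EGFL7	human
Epithelial cells	EPCAM	human
Epithelial cells	KRT8	human
Epithelial cells	KRT18	human
Epithelial cells	KRT19	human
Epithelial cells	CDH1	human
Epithelial cells	KRT5	human
Epithelial cells	MUC1	human
Epithelial cells	CLDN4	human
Platelets	PF4	human
Platelets	PPBP	human
Platelets	ITGA2B	human
Platelets	GP9	human
Platelets	TUBB1	human
Platelets	GP1BA	human
Platelets	MPL	human
Platelets	THBS1	human
Erythroid cells	HBB	human
Erythroid cells	HBA1	human
Erythroid cells	HBA2	human
Erythroid cells	GYPA	human
Erythroid cells	ALAS2	human
Erythroid cells	SLC4A1	human
Erythroid cells	KLF1	human
Erythroid cells	EPOR	human
Mast cells	TPSAB1	human
Mast cells	TPSB2	human
Mast cells	CPA3	human
Mast cells	MS4A2	human
Mast cells	KIT	human
Mast cells	CMA1	human
Mast cells	HDC	human
Mast cells	GATA2	human
Plasma cells	SDC1	human
Plasma cells	MZB1	human
Plasma cells	XBP1	human
Plasma cells	JCHAIN	human
Plasma cells	PRDM1	human
Plasma cells	DERL3	human
Plasma cells	TNFRSF17	human
Plasma cells	IGHG1	human
Astrocytes	GFAP	human
Astrocytes	AQP4	human
Astrocytes	SLC1A3	human
Astrocytes	ALDH1L1	human
Astrocytes	S100B	human
Astrocytes	GJA1	human
Astrocytes	FGFR3	human
Astrocytes	SOX9	human
Neurons	SNAP25	human
Neurons	SYT1	human
Neurons	RBFOX3	human
Neurons	MAP2	human
Neurons	NEFL	human
Neurons	SYP	human
Neurons	GRIN1	human
Neurons	TUBB3	human
Hepatocytes	ALB	human
Hepatocytes	APOA1	human
Hepatocytes	TF	human
Hepatocytes	CYP3A4	human
Hepatocytes	ASGR1	human
Hepatocytes	FGA	human
Hepatocytes	FGB	human
Hepatocytes	APOB	human
Smooth muscle cells	ACTA2	human
Smooth muscle cells	MYH11	human
Smooth muscle cells	TAGLN	human
Smooth muscle cells	CNN1	human
Smooth muscle cells	DES	human
Smooth muscle cells	LMOD1	human
Smooth muscle cells	MYLK	human
Smooth muscle cells	PLN	human
Pancreatic acinar cells	PRSS1	human
Pancreatic acinar cells	CPA1	human
Pancreatic acinar cells	CELA3A	human
Pancreatic acinar cells	CTRB1	human
Pancreatic acinar cells	PNLIP	human
Pancreatic acinar cells	CLPS	human
Pancreatic acinar cells	CELA2A	human
Pancreatic acinar cells	AMY2A	human
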