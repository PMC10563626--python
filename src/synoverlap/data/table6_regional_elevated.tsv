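gene_id	region	set_labels
CHRM4	cerebral cortex	SCZ,ASD
CHRNA2	thalamus	SCZ
DGKZ	cerebral cortex	SCZ,ASD
DGKZ	hippocampal formation	SCZ,ASD
DGKZ	amygdala	SCZ,ASD
GRIN2A	cerebral cortex	SCZ,ASD
HCN1	cerebral cortex	SCZ,ASD
IGSF9B	cerebellum	PD,SCZ,ASD
KCNB1	cerebral cortex	SCZ
MCTP2	cerebral cortex	PD
MEF2C	cerebral cortex	AD,SCZ,ASD
MEF2C	hippocampal formation	AD,SCZ,ASD
MEF2C	amygdala	AD,SCZ,ASD
NRGN	cerebral cortex	SCZ,ASD
PCLO	cerebellum	SCZ
PRRT1	cerebral cortex	SCZ,ASD
PRRT1	hippocampal formation	SCZ,ASD
PRRT1	amygdala	SCZ,ASD
RIMS1	cerebellum	SCZ,ASD
RPL9	cerebral cortex	PANX1
SCGN	cerebellum	SCZ,ASD
SCGN	hippocampal formation	SCZ,ASD
SCGN	hypothalamus	SCZ,ASD
SHISA8	cerebellum	SCZ
SLC18A2	pons	PANX1
SLC18A2	midbrain	PANX1
SLC18A2	hypothalamus	PANX1
SLC4A10	cerebral cortex	SCZ
STX1B	cerebral cortex	PD
SYNGAP1	cerebral cortex	SCZ,ASD
SYNGAP1	hippocampal formation	SCZ,ASD
SYNGAP1	amygdala	SCZ,ASD
TANC2	cerebral cortex	PANX1
TANC2	hippocampal formation	PANX1
TANC2	amygdala	PANX1
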