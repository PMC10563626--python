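condition	gene_symbol	description	asd_shared
Parkinson's disease	Nsf	Vesicle-fusing ATPase	0
Alzheimer's disease	Usp6nl	USP6 N-terminal-like protein	0
schizophrenia	Acads	Short-chain specific acyl-CoA dehydrogenase, mitochondrial	1
schizophrenia	Actr1a	Alpha-centractin	1
schizophrenia	Agpat1	1-acyl-sn-glycerol-3-phosphate acyltransferase alpha	1
schizophrenia	Ddx39b	Spliceosome RNA helicase Ddx39b	1
schizophrenia	Cnot1	CCR4-NOT transcription complex subunit 1	1
schizophrenia	Csrp2	Cysteine and glycine-rich protein 2	0
schizophrenia	Etf1	Eukaryotic peptide chain release factor subunit 1	0
schizophrenia	Gmip	GEM-interacting protein	0
schizophrenia	Gna12	Guanine nucleotide-binding protein subunit alpha-12	0
schizophrenia	Gnl1	Guanine nucleotide-binding protein-like 1	1
schizophrenia	Gulo	L-gulonolactone oxidase	0
schizophrenia	Hspa1b	Heat shock 70 kDa protein 1B	1
schizophrenia	Hspa1l	Heat shock 70 kDa protein 1-like	1
schizophrenia	Hspd1	60 kDa heat shock protein, mitochondrial	1
schizophrenia	Hspe1	10 kDa heat shock protein, mitochondrial	1
schizophrenia	Lsm1	U6 snRNA-associated Sm-like protein LSm1	0
schizophrenia	Mapk3	Mitogen-activated protein kinase 3	0
schizophrenia	Plcl1	Inactive phospholipase C-like protein 1	1
schizophrenia	Psmd6	26S proteasome non-ATPase regulatory subunit 6	0
schizophrenia	St13	Hsc70-interacting protein	1
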