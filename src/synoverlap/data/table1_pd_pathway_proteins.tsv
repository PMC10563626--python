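gene_symbol	description	protein_class	apoptosis_signaling	fgf_signaling	cckr_signaling
Hspa1b	Heat shock 70 kDa protein 1B	Hsp70 family chaperone	1	0	0
Hspa1l	Heat shock 70 kDa protein 1-like	Hsp70 family chaperone	1	0	0
Hspa2	Heat shock-related 70 kDa protein 2	Hsp70 family chaperone	1	0	0
Mapk1	Mitogen-activated protein kinase 1	Protein modifying enzyme	1	1	1
Mapk3	Mitogen-activated protein kinase 3	Protein modifying enzyme	1	1	1
Mcm5	DNA replication licensing factor MCM5	DNA metabolism protein	1	0	0
Psma3	Proteasome subunit alpha type-3	Protein modifying enzyme	0	0	0
Septin1	Septin-1	Cytoskeletal protein	0	0	0
Septin2	Septin-2	Cytoskeletal protein	0	0	0
Sfn	14-3-3 protein sigma	Scaffold/adaptor protein	0	1	0
Ywhab	14-3-3 protein beta/alpha	Scaffold/adaptor protein	0	1	1
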