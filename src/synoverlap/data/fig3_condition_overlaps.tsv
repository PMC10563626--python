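signature	genes
AD&PD	APOE,MAPT
AD&SCZ	ADAM10,PTK2B
PD&SCZ	DLG2,FYN
AD&SCZ&ASD	CLU,MEF2C
PD&SCZ&ASD	IGSF9B
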