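domain	term_id	label	fold_enrichment	p_value	asd	scz	pd	ad
CC	GO:0032279	Asymmetric synapse	7.07	5.41E-06	1	1	1	1
CC	GO:0030139	Endocytic vesicle	5.25	1.11E-03	0	0	1	1
CC	GO:0070382	Exocytic vesicle	7.82	5.22E-05	1	1	1	0
CC	GO:0098978	Glutamatergic synapse	8.06	2.12E-07	1	1	1	1
CC	GO:0098984	Neuron to neuron synapse	6.58	1.07E-05	1	1	1	1
CC	GO:0098794	Postsynapse	7.5	9.44E-13	1	1	1	1
CC	GO:0014069	Postsynaptic density	7.2	4.62E-06	1	1	1	1
CC	GO:0099572	Postsynaptic specialization	7.29	1.54E-06	1	1	1	1
CC	GO:0098793	Presynapse	5.14	2.23E-05	1	1	1	0
CC	GO:0030133	Transport vesicle	5.05	2.84E-04	1	1	1	0
BP	GO:0034329	Cell junction assembly	6.54	5.93E-03	0	1	0	1
BP	GO:0034330	Cell junction organization	4.35	1.77E-02	1	1	1	1
BP	GO:0051234	Establishment of localization	2.26	4.96E-05	1	1	1	0
BP	GO:0060627	Regulation of vesicle-mediated transport	4.25	1.23E-02	1	1	1	1
BP	GO:0006810	Transport	2.3	2.75E-05	1	1	1	0
BP	GO:0016192	Vesicle-mediated transport	3.27	5.64E-04	0	1	1	0
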