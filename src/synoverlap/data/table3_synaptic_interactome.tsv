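uniprot_id	gene_name	description
P62196	Psmc5	26S protease regulatory subunit 8
P62270	Rps18	40S ribosomal protein S18
P97351	Rps3a	40S ribosomal protein S3a
Q6ZWN5	Rps9	40S ribosomal protein S9
P97789	Xrn1	5'-3' exoribonuclease 1
P14869	Rplp0	60S acidic ribosomal protein P0
P99027	Rplp2	60S acidic ribosomal protein P2
P35980	Rpl18	60S ribosomal protein L18
P62717	Rpl18a	60S ribosomal protein L18a
P67984	Rpl22	60S ribosomal protein L22
Q9D8E6	Rpl4	60S ribosomal protein L4
P12970	Rpl7a	60S ribosomal protein L7a
P51410	Rpl9	60S ribosomal protein L9
P20782	Chrne	Acetylcholine receptor subunit epsilon
P68033	Actc1	Actin, alpha cardiac muscle 1
Q9D898	Arpc5l	Actin-related protein 2/3 complex subunit 5-like protein
Q99JY9	Actr3	Actin-related protein 3
Q9CQW2	Arl8b	ADP-ribosylation factor-like protein 8B
Q9QZQ1	Mllt4	Afadin
A2ASQ1	Agrn	Agrin
Q7TPR4	Actn1	Alpha-actinin-1
Q91ZU6	Dst	Bullous pemphigoid antigen 1
P28652	Camk2b	Calcium/calmodulin-dependent protein kinase type II subunit beta
P35564	Canx	Calnexin
O08585	Clta	Clathrin light chain A
Q8BZN6	Dock10	Dedicator of cytokinesis protein 10
O08553	Dpysl2	Dihydropyrimidinase-related protein 2
Q62188	Dpysl3	Dihydropyrimidinase-related protein 3
Q62418	Dbnl	Drebrin-like protein
Q91V17	Znrf1	E3 ubiquitin-protein ligase ZNRF1
P70372	Elavl1	ELAV-like protein 1
P58252	Eef2	Elongation factor 2
Q91VC3	Eif4a3	Eukaryotic initiation factor 4A-III
Q8JZQ9	Eif3b	Eukaryotic translation initiation factor 3 subunit B
Q6NZJ6	Eif4g1	Eukaryotic translation initiation factor 4 gamma 1
Q62448	Eif4g2	Eukaryotic translation initiation factor 4 gamma 2
Q9CS72	Filip1	Filamin-A-interacting protein 1
P17183	Eno2	Gamma-enolase
Q03391	Grin2d	Glutamate [NMDA] receptor subunit epsilon-4
P21278	Gna11	Guanine nucleotide-binding protein subunit alpha-11
Q99020	Hnrnpab	Heterogeneous nuclear ribonucleoprotein A/B
P70333	Hnrnph2	Heterogeneous nuclear ribonucleoprotein H2
P61979	Hnrnpk	Heterogeneous nuclear ribonucleoprotein K
Q8VD75	Hip1	Huntingtin-interacting protein 1
Q60960	Kpna1	Importin subunit alpha-1
O35711	Ppfibp2	Liprin-beta-2
P60755	Mdga2	MAM domain-containing glycosylphosphatidylinositol anchor protein 2
P27546	Map4	Microtubule-associated protein 4
P63085	Mapk1	Mitogen-activated protein kinase 1
P53986	Slc16a1	Monocarboxylate transporter 1
P57787	Slc16a3	Monocarboxylate transporter 4
P21271	Myo5b	Myosin-Vb
P26645	Marcks	Myristoylated alanine-rich C-kinase substrate
Q04690	Nf1	Neurofibromin
P26883	Fkbp1a	Peptidyl-prolyl cis-trans isomerase FKBP1A
Q99K51	Pls3	Plastin-3
O35129	Phb2	Prohibitin-2
O70435	Psma3	Proteasome subunit alpha type-3
A2A690	Tanc2	Protein TANC2
P62492	Rab11a	Ras-related protein Rab-11A
P46638	Rab11b	Ras-related protein Rab-11B
P35283	Rab12	Ras-related protein Rab-12
Q91V41	Rab14	Ras-related protein Rab-14
Q8K386	Rab15	Ras-related protein Rab-15
O35963	Rab33b	Ras-related protein Rab-33B
Q6PHN9	Rab35	Ras-related protein Rab-35
Q9CZT8	Rab3b	Ras-related protein Rab-3B
P62823	Rab3c	Ras-related protein Rab-3C
P35276	Rab3d	Ras-related protein Rab-3D
P56371	Rab4a	Ras-related protein Rab-4A
P35279	Rab6a	Ras-related protein Rab-6A
P61294	Rab6b	Ras-related protein Rab-6B
P55258	Rab8a	Ras-related protein Rab-8A
P62835	Rap1a	Ras-related protein Rap-1A
Q9ES97	Rtn3	Reticulon-3
P18654	Rps6ka3	Ribosomal protein S6 kinase alpha-3
P42209	Sept1	Septin-1
P42208	Sept2	Septin-2
Q7TNP2	Ppp2r1b	Serine/threonine-protein phosphatase 2A 65 kDa regulatory subunit A beta isoform
P63087	Ppp1cc	Serine/threonine-protein phosphatase PP1-gamma catalytic subunit
Q91Z67	Srgap2	SLIT-ROBO Rho GTPase-activating protein 2
O35316	Slc6a6	Sodium- and chloride-dependent taurine transporter
Q8BRU6	Slc18a2	Synaptic vesicular amine transporter
O08992	Sdcbp	Syntenin-1
P83510	Tnik	Traf2 and NCK-interacting protein kinase
P68369	Tuba1a	Tubulin alpha-1A chain
A2AAE1	Kiaa1109	Uncharacterized protein KIAA1109
P59016	Vps33b	Vacuolar protein sorting-associated protein 33B
P46460	Nsf	Vesicle-fusing ATPase
O08547	Sec22b	Vesicle-trafficking protein SEC22b
Q60931	Vdac3	Voltage-dependent anion-selective channel protein 3
Q9Z1G4	Atp6v0a1	V-type proton ATPase 116 kDa subunit a isoform 1
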