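gene_id	fc1	fc2	log2_fc2_fc1	fc3	fc4	log2_fc4_fc3	gene_name	description
Zjn_sc00047.1.g03800.1.sm.mk	5.10	11.14	1.13	1.77	1.05	−0.75	\	Hypothetical protein
Zjn_sc00022.1.g04760.1.sm.mk	0.23	0.21	−0.10	1.02	0.22	−2.23	\	WEB family protein At5g16730, chloroplastic
Zjn_sc00015.1.g05160.1.sm.mkhc	0.12	0.09	−0.46	0.98	0.32	−1.62	\	\
Zjn_sc00089.1.g00090.1.am.mk	0.36	0.17	−1.11	1.00	0.42	−1.25	4CL1	4-coumarate-CoA ligase 1
Zjn_sc00109.1.g00965.1.br	6.83	16.91	1.31	1.74	1.93	0.15	BBE	Berberine bridge enzyme-like Cyn d 4
Zjn_sc00018.1.g01620.1.sm.mkhc	0.16	0.35	1.12	0.70	0.51	−0.46	CCR1	Cinnamoyl-CoA reductase 2
Zjn_sc00090.1.g01530.1.sm.mkhc	2.90	3.10	0.10	0.84	2.93	1.80	CEQORH	Chloroplast envelope quinone oxidoreductase homolog
Zjn_sc00109.1.g00880.1.sm.mk	21.70	22.30	0.04	1.85	0.90	−1.04	CHT2	Chitinase 2-like
Zjn_sc00102.1.g00830.1.am.mk	38.47	16.84	−1.19	2.67	0.80	−1.74	CHT8	Chitinase 8
Zjn_sc00045.1.g00590.1.sm.mk	0.14	0.01	−3.84	0.80	0.56	−0.51	CYP74A4	Allene oxide synthase 4
Zjn_sc00013.1.g09290.1.am.mkhc	0.71	3.73	2.40	0.77	4.19	2.45	ephA	Epoxide hydrolase A-like
Zjn_sc00012.1.g02790.1.am.mkhc	0.31	0.40	0.34	0.86	0.42	−1.04	FPS	Farnesyl pyrophosphate synthase
Zjn_sc00049.1.g01050.1.am.mk	0.23	0.11	−1.06	0.69	0.39	−0.85	GLIP	GDSL esterase/lipase
Zjn_sc00048.1.g00650.1.sm.mkhc	0.43	0.42	−0.05	0.48	1.29	1.42	GSH2	Glutathione synthetase, chloroplastic-like isoform X1
Zjn_sc00003.1.g11520.1.sm.mk	0.33	0.21	−0.62	0.52	1.20	1.19	H2AV	Probable histone H2A variant 1
Zjn_sc00003.1.g07680.1.sm.mkhc	2.91	6.27	1.11	0.98	2.00	1.03	HB2	Non-symbiotic hemoglobin
Zjn_sc00011.1.g02850.1.sm.mkhc	0.22	0.09	−1.25	1.10	0.53	−1.06	LAMP1	Probable glutamate carboxypeptidase LAMP1
Zjn_sc00026.1.g00700.1.sm.mk	104.07	51.72	−1.01	3.53	1.63	−1.11	LEA14-A	Late embryogenesis abundant protein Lea14-A-like
Zjn_sc00075.1.g00370.1.sm.mk	0.43	0.59	0.45	0.54	1.11	1.03	LOX5	Linoleate 9S-lipoxygenase 5
Zjn_sc00034.1.g03480.1.am.mk	0.11	0.13	0.19	0.70	0.32	−1.16	LTP	Protease inhibitor/seed storage/LTP family protein precursor
Zjn_sc00011.1.g06270.1.am.mk	\	0.04	\	0.62	0.15	−2.06	MEE55	Serinc-domain containing serine and sphingolipid biosynthesis protein
Zjn_sc00155.1.g00490.1.am.mk	0.05	0.22	2.12	0.42	0.31	−0.43	NRT2.1	High-affinity nitrate transporter 2.1-like
Zjn_sc00152.1.g00350.1.sm.mk	0.05	0.15	1.43	0.43	0.46	0.08	NRT2.1	High-affinity nitrate transporter 2.1-like
Zjn_sc00052.1.g00190.1.sm.mkhc	0.03	0.09	1.37	0.95	0.57	−0.75	OMT2	O-methyltransferase 2
Zjn_sc00005.1.g03630.1.sm.mkhc	2.70	3.06	0.18	0.98	1.98	1.02	PFK4	ATP-dependent 6-phosphofructokinase 4 chloroplastic
Zjn_sc00009.1.g08860.1.sm.mkhc	0.15	0.06	−1.28	0.88	0.66	−0.42	PLDα2	Phospholipase D alpha 2
Zjn_sc00026.1.g02680.1.am.mk	0.45	0.08	−2.46	1.40	0.38	−1.89	PNC1	Cationic peroxidase 1-like
Zjn_sc00143.1.g00490.1.sm.mkhc	1.69	3.15	0.90	0.84	1.83	1.11	pro-resilin	Pro-resilin precursor
Zjn_sc00093.1.g00470.1.sm.mkhc	0.06	0.03	−1.13	1.29	0.59	−1.12	PXG4	Peroxygenase 4
Zjn_sc00207.1.g00180.1.cf.mkhc	0.29	0.23	−0.33	0.29	0.69	1.25	RPM1	Disease resistance protein RPM1
Zjn_sc00152.1.g00230.1.sm.mk	0.48	0.45	−0.10	0.33	1.25	1.92	RPPR5	Pentatricopeptide repeat-containing protein At2g37230
Zjn_sc00004.1.g14080.1.sm.mkhc	0.09	0.08	−0.08	0.22	0.45	1.06	STY8	Serine/threonine-protein kinase STY8
Zjn_sc00022.1.g06510.1.sm.mkhc	0.19	0.24	0.29	0.99	0.47	−1.06	TIP2-1	Aquaporin TIP2-1
Zjn_sc00007.1.g10230.1.sm.mkhc	0.28	0.35	0.32	0.99	0.47	−1.06	TIP2-1	Aquaporin TIP2-1
Zjn_sc00009.1.g09140.1.sm.mk	0.20	0.07	−1.55	0.77	0.48	−0.69	TUBB2	Tubulin beta-2 chain
Zjn_sc00096.1.g01880.1.am.mk	54.13	86.21	0.67	4.61	2.25	−1.03	XIP2	Xylanase inhibitor protein 2-like
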