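# Published characteristics of the 19 barley thaumatin-like protein (HvTLP) genes.
# Transcript accessions are Ensembl Plants barley (Hordeum vulgare) identifiers.
gene_symbol	accession	cds_length_bp	aa_length	pI	mw_kda	n_cysteine	chromosome	genomic_start	genomic_end	exon_count	localization	signal_peptide	tm_count
HvTLP1	HORVU7Hr1G122120.1	522	173	4.33	17.548	10	7H	655448674	655449693	2	Extracellular	N-terminal	1
HvTLP2	HORVU7Hr1G122100.1	522	173	4.51	17.576	10	7H	655345402	655345932	1	Extracellular	N-terminal	1
HvTLP3	HORVU5Hr1G017530.1	528	175	5.02	18.048	10	5H	67689233	67690149	1	Extracellular	N-terminal	1
HvTLP4	HORVU5Hr1G005290.1	690	229	6.45	24.325	10	5H	8764295	8765150	1	Extracellular	N-terminal	1
HvTLP5	HORVU5Hr1G005180.4	744	247	6.48	26.062	16	5H	8598500	8736900	2	Extracellular	N-terminal	1
HvTLP6	HORVU5Hr1G005180.6	681	226	7.33	23.725	16	5H	8614116	8615298	1	Extracellular	N-terminal	1
HvTLP7	HORVU5Hr1G051970.4	738	245	8.13	25.61	16	5H	406435574	406436533	2	Extracellular	N-terminal	0
HvTLP8	HORVU4Hr1G002650.2	768	255	8.11	26.821	16	4H	5073727	5074962	1	Extracellular	N-terminal	1
HvTLP9	HORVU7Hr1G057350.1	771	256	4.83	26.959	16	7H	248978165	248980455	2	Extracellular	N-terminal	1
HvTLP10	HORVU5Hr1G005190.1	681	226	5.57	23.177	16	5H	8603703	8604574	1	Extracellular	N-terminal	0
HvTLP11	HORVU1Hr1G005760.1	786	261	5.18	26.106	17	1H	12508776	12510365	1	Extracellular	N-terminal	0
HvTLP12	HORVU5Hr1G084650.2	840	279	6.83	27.804	18	5H	573025822	573026929	1	Extracellular	N-terminal	1
HvTLP13	HORVU3Hr1G086510.1	753	250	7.47	26.017	17	3H	617523511	617524882	1	Extracellular	N-terminal	0
HvTLP14	HORVU3Hr1G012100.9	1026	341	5.33	38.477	22	3H	26305708	26310551	1	Plasma membrane	N-terminal	2
HvTLP15	HORVU4Hr1G066130.4	780	259	4.79	25.744	16	4H	550925586	550926443	2	Extracellular	N-terminal	0
HvTLP16	HORVU1Hr1G021650.3	777	258	8.43	27.097	17	1H	88073476	88075764	2	Extracellular	N-terminal	1
HvTLP17	HORVU3Hr1G002210.5	1080	359	7.72	40.844	24	3H	4627368	4637925	2	Plasma membrane	N-terminal	1
HvTLP18	HORVU5Hr1G112160.1	960	319	4.85	31.991	16	5H	638398994	638401180	3	Extracellular	N-terminal	0
HvTLP19	HORVU4Hr1G063730.7	789	262	6.07	27.062	19	4H	533492849	533494381	4	Extracellular	N-terminal	0
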