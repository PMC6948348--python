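uniprot_id	protein_name	gene_symbol	degree
P03372	Estrogen receptor	ESR1	25
P04150	Glucocorticoid receptor	NR3C1	13
P05067	Amyloid-beta A4 protein	APP	15
P06401	Progesterone receptor	PGR	4
P06746	DNA polymerase beta	POLB	4
P10275	Androgen receptor	AR	27
P10636	Microtubule-associated protein tau	MAPT	13
P11413	Glucose-6-phosphate 1-dehydrogenase	G6PD	13
P11473	Vitamin D3 receptor	VDR	13
P37231	Peroxisome proliferator-activated receptor gamma	PPARG	23
Q08828	Adenylate cyclase type 1	ADCY1	12
Q13887	Krueppel-like factor 5	KLF5	1
Q9NYA1	Sphingosine kinase 1	SPHK1	3
Q9UBM7	7-dehydrocholesterol reductase	DHCR7	14
P00915	Carbonic anhydrase 1	CA1	6
P00918	Carbonic anhydrase 2	CA2	17
P04798	Cytochrome P450 1A1	CYP19A1	11
Q07973	1,25-dihydroxyvitamin D(3) 24-hydroxylase, mitochondrial	CYP24A1	5
Q92731	Estrogen receptor beta	ESR2	18
O15439	Multidrug resistance-associated protein 4	ABCC4	4
O15118	NPC intracellular cholesterol transporter 1	NPC1	4
Q96RI1	Bile acid receptor	NR1H4	4
Q12908	Ileal sodium/bile acid cotransporter	SLC10A2	6
P51449	Nuclear receptor ROR-gamma	RORC	4
O75751	Solute carrier family 22 member 3	SLC22A3	5
P04278	Sex hormone-binding globulin	SHBG	5
Q12772	Sterol regulatory element-binding protein 2	SREBF2	4
P02774	Vitamin D-binding protein	GC	2
O95622	Adenylate cyclase type 5	ADCY5	13
P04798	Cytochrome P450 1A1	CYP1A1	12
P05091	Aldehyde dehydrogenase, mitochondrial	ALDH2	11
P05177	Cytochrome P450 1A2	CYP1A2	10
P07900	Heat shock protein HSP 90-alpha	HSP90AA1	16
P09917	Arachidonate 5-lipoxygenase	ALOX5	13
P11309	Serine/threonine-protein kinase pim-1	PIM1	15
P18031	Tyrosine-protein phosphatase non-receptor type 1	PTPN1	18
P19438	Tumor necrosis factor receptor superfamily member 1A	TNFRSF1A	9
P23219	Prostaglandin G/H synthase 1	PTGS1	14
P24941	Cyclin-dependent kinase 2	CDK2	14
P33527	Multidrug resistance-associated protein 1	ABCC1	14
P35228	Nitric oxide synthase, inducible	NOS2	18
P35354	Prostaglandin G/H synthase 2	PTGS2	19
P36888	Receptor-type tyrosine-protein kinase FLT3	FLT3	7
P47989	Xanthine dehydrogenase/oxidase (includes xanthine dehydrogenase)	XDH	12
P48736	Phosphatidylinositol 4,5-bisphosphate 3-kinase catalytic subunit gamma isoform	PIK3CG	9
P49841	Glycogen synthase kinase-3 beta	GSK3B	15
P68400	Casein kinase II subunit alpha	CSNK2A1	4
Q00534	Cyclin-dependent kinase 6	CDK6	12
Q12791	Calcium-activated potassium channel subunit alpha-1	KCNMA1	4
Q12882	Dihydropyrimidine dehydrogenase [NADP(+)]	DPYD	4
Q16539	Mitogen-activated protein kinase 14	MAPK14	15
Q16678	Cytochrome P450 1B1	CYP1B1	14
Q9BVA1	Tubulin beta-2B chain	TUBB2B	15
Q9UNQ0	ATP-binding cassette subfamily G member 2	ABCG2	13
Q9Y263	Phospholipase A-2-activating protein	PLAA	12
P00519	Tyrosine-protein kinase ABL1	ABL1	7
P35869	Aryl hydrocarbon receptor	AHR	8
O43570	Carbonic anhydrase 12	CA12	18
P51679	C-C chemokine receptor type 4	CCR4	10
P13569	Cystic fibrosis transmembrane conductance regulator	CFTR	2
P16220	Cyclic AMP-responsive element-binding protein 1	CREB1	12
P53355	Death-associated protein kinase 1	DAPK1	11
P60568	Interleukin-2	IL2	18
P51812	Ribosomal protein S6 kinase alpha-3	RPS6KA3	11
P43405	Tyrosine-protein kinase SYK	SYK	4
Q04760	Lactoylglutathione lyase	GLO1	15
P08183	Multidrug resistance protein 1	ABCB1	12
P14174	Macrophage migration inhibitory factor	MIF	3
P15559	NAD(P)H dehydrogenase [quinone] 1	NQO1	6
O14746	Telomerase reverse transcriptase	TERT	11
P02766	Transthyretin	TTR	12
P15692	Vascular endothelial growth factor A	VEGFA	17
P00734	Prothrombin	F2	9
P08514	Integrin alpha-IIb	ITGA2B	2
P08842	Steryl-sulfatase	STS	3
P15090	Fatty acid-binding protein, adipocyte	FABP4	2
P28223	5-hydroxytryptamine receptor 2A	HTR2A	8
Q16790	Carbonic anhydrase 9	CA9	8
P05230	Fibroblast growth factor 1	FGF1	7
P09038	Fibroblast growth factor 2	FGF2	7
P10145	Interleukin-8	CXCL8	1
P09382	Galectin-1	LGALS1	2
P17931	Galectin-3	LGALS3	4
P01112	GTPase HRas	HRAS	1
P14679	Tyrosinase	TYR	9
P08253	72 kDa type IV collagenase	MMP2	4
P08254	Stromelysin-1	MMP3	4
P09874	Poly [ADP-ribose] polymerase 1	PARP1	2
P14780	Matrix metalloproteinase-9	MMP9	4
P24864	G1/S-specific cyclin-E1	CCNE1	4
P39900	Macrophage metalloelastase	MMP12	4
O60285	NUAK family SNF1-like kinase 1	NUAK1	6
P37840	Alpha-synuclein	SNCA	5
P11712	Cytochrome P450 2C9	CYP2C9	3
P51684	C-C chemokine receptor type 6	CCR6	2
P27695	DNA-(apurinic or apyrimidinic site) lyase	APEX1	4
P11388	DNA topoisomerase 2-alpha	TOP2A	5
O60218	Aldo-keto reductase family 1 member B10	AKR1B10	9
P25116	Proteinase-activated receptor 1	F2R	5
P43681	Neuronal acetylcholine receptor subunit alpha-4	CHRNA4	4
P63151	Serine/threonine-protein phosphatase 2A 55 kDa regulatory subunit B alpha isoform	PPP2R2A	3
Q04206	Transcription factor p65	RELA	3
P14867	Gamma-aminobutyric acid receptor subunit alpha-1	GABRA1	3
P06881	Calcitonin gene-related peptide 1	CALCA	1
P13501	C-C motif chemokine 5	CCL5	1
P32245	Melanocortin receptor 4	MC4R	1
P68104	Elongation factor 1-alpha 1	EEF1A1	3
Q13822	Ectonucleotide pyrophosphatase/phosphodiesterase family member 2	ENPP2	3
Q9Y251	Heparanase	HPSE	3
P53985	Monocarboxylate transporter 1	SLC16A1	2
P11509	Cytochrome P450 2A6	CYP2A6	3
Q15788	Nuclear receptor coactivator 1	NCOA1	1
Q99814	Endothelial PAS domain-containing protein 1	EPAS1	3
P00533	Epidermal growth factor receptor	EGFR	4
Q16665	Hypoxia-inducible factor 1-alpha	HIF1A	2
P40926	Malate dehydrogenase, mitochondrial	MDH2	2
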