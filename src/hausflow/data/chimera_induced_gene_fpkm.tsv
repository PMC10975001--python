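unigene_id	gene	annotation	TH	THC	PC	P
Cluster-28098.16	1433D_SOYBN	14-3-3 protein	277.4	291.9	0.2	0.0
Cluster-30463.1	ACT11_ARATH	Actin	0.3	5.2	1.7	0.0
Cluster-30642.1	ACT1_ORYSI	Actin	0.3	1.2	7.2	0.1
Cluster-26673.1	AMT11_SOLLC	Ammonium Transporter Family	234.2	428.8	2.1	0.0
Cluster-37206.1	CAF1K_ARATH	CAF1 family ribonuclease	294.3	412.9	0.2	0.0
Cluster-28144.0	CAES_ARATH	Carbohydrate esterase, sialic acid-specific acetylesterase	34.6	179.0	1.2	0.0
Cluster-40689.0	CHIT_PERAE	Chitinase class I	82.1	604.1	2.2	0.0
Cluster-2905.1	ALPL_ARATH	DDE superfamily endonuclease	243.2	350.0	2.6	0.0
Cluster-33686.3	--	Dehydrin	3321	6625	4.0	0.1
Cluster-25215.6	EP1L4_ARATH	D-mannose binding lectin	499.1	735.5	1.1	0.0
Cluster-28520.1	DUF4228	Domain of unknown function	309.4	405.8	0.3	0.0
Cluster-31749.0	DUF4723	Domain of unknown function	50.4	604.3	2.0	0.1
Cluster-28199.1	ESSS	ESSS subunit of NADH:ubiquinone oxidoreductase	475.7	553.4	0.6	0.0
Cluster-86868.1	ERM	Ezrin/radixin/moesin family	0.0	0.1	0.1	0.0
Cluster-28808.1	BBE21_ARATH	FAD binding domain	80.6	336.6	1.5	0.0
Cluster-31390.0	CASL1_CANSA	FAD binding domain	88.5	126.5	1.7	0.0
Cluster-24876.1	DUF716	Family of unknown function	15.3	18.8	0.7	0.0
Cluster-26009.1	FB119_ARATH	F-box-like	34.9	118.7	0.2	0.0
Cluster-20986.5	GSTF_HYOMU	Glutathione S-transferase, C-terminal domain	249.2	502.4	1.3	0.0
Cluster-20103.7	GADPH	Glyceraldehyde 3-phosphate dehydrogenase	395	576.7	0.8	0.0
Cluster-23641.1	XTH23_ARATH	Glycosyl hydrolases family 16	460.3	981.2	3.8	0.0
Cluster-26468.1	ERLL1_ARATH	Hydrophobic seed protein	136.7	490.7	0.1	0.0
Cluster-29998.1	LEA14_GOSHI	Late embryogenesis abundant protein	425.5	842.2	0.2	0.0
Cluster-28203.4	GILP_ARATH	LITAF-like zinc ribbon domain	67.1	80.9	0.1	0.0
Cluster-27980.8	FPPS1_LUPAL	Polyprenyl synthetase	43.3	217.8	0.2	0.0
Cluster-29223.2	MSK3_MEDSA	Protein kinase domain	204.5	265.7	1.2	0.0
Cluster-26011.1	CRK7_ARATH	Protein tyrosine kinase	37.4	46.4	0.5	0.0
Cluster-15047.1	SPE1_PEA	Pyridoxal-dependent decarboxylase	489.5	618.4	1.0	0.0
Cluster-25493.2	RL72_ARATH	Ribosomal L30 N-terminal domain	323.6	331.5	0.3	0.0
Cluster-28869.1	RL72_ARATH	Ribosomal L30 N-terminal domain	139.9	210.5	0.1	0.0
Cluster-27350.3	RL3_ORYSJ	Ribosomal protein L3	1144	1163	0.7	0.0
Cluster-25988.1	RL262_ARATH	Ribosomal proteins L26	382.7	481.3	0.3	0.0
Cluster-29252.2	RICI_RICCO	Ricin-type beta-trefoil lectin domain	765.1	2370	1.4	0.0
Cluster-29448.5	CSE_ARATH	Serine aminopeptidase, S33	6.9	43.7	0.0	0.0
Cluster-72533.2	STC	Stanniocalcin family	0.1	0.5	1.0	0.9
Cluster-37697.0	TCTP_ELAGV	Translationally controlled tumour protein	8295	9521	5.7	0.1
Cluster-25717.1	SSRA_ARATH	Translocon-associated protein (TRAP) alpha	89.6	106.1	0.9	0.0
Cluster-27790.5	LHT1_ARATH	Transmembrane amino acid transporter protein	32.4	138.4	0.9	0.0
Cluster-30943.0	TBA_EUGGR	Tubulin C-terminal domain	0.1	0.5	2.2	0.0
Cluster-43188.0	TBB_CHLIN	Tubulin/FtsZ family, GTPase domain	0.4	1.7	4.4	0.1
Cluster-26035.2	U73D1_ARATH	UDP-glucoronosyl and UDP-glucosyl transferase	53.1	120.9	0.2	0.0
Cluster-44341.8	ZFP	Zinc finger C-x8-C-x5-C-x3-H type	0.0	0.1	0.3	0.0
Cluster-27579.1	EXLB1_ARATH	Expansin	294.2	1724	1.2	0.0
Cluster-92147.2	ARI4_ARATH	E3 ubiquitin-protein ligase	0.1	0.1	0.7	0.1
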