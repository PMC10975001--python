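unigene_id	gene	annotation	TH	THC	PC	P
Cluster-12122.6	R10A	60S ribosomal protein L10a	924.6	1404.5	3.6	0.0
Cluster-13284.0	RAN1	GTP-binding nuclear protein Ran1	452.4	907.1	8.0	0.0
Cluster-14148.4	TIC32	Short-chain dehydrogenase TIC 32, chloroplastic	982.1	2251.9	4.4	0.0
Cluster-16015.3	METK5	S-adenosylmethionine synthase 5	433.0	3149.3	5.5	0.0
Cluster-16686.0	WRK40	Probable WRKY transcription factor 40	1142.9	1043.8	10.9	0.0
Cluster-16839.1	SUNN	Leucine-rich repeat receptor-like kinase	49.3	46.8	4.9	0.0
Cluster-1723.0	UNC13	Protein unc-13 homolog	32.9	46.3	6.2	0.0
Cluster-18022.0	ORM1	ATORM1, OROSOMUCOID-LIKE 1 ORM1	125.2	148.4	6.4	0.0
Cluster-22492.4	PPA29	Probable inactive purple acid phosphatase 29	917.8	1041.0	4.6	0.0
Cluster-23922.0	LTI6B	Hydrophobic protein LTI6B	365.2	891.6	4.6	0.0
Cluster-23995.0	EMB8	Embryogenesis-associated protein EMB8	88.3	49.9	11.0	0.0
Cluster-24355.1	KNAP3	Homeobox protein knotted-1-like 3	257.7	238.1	5.9	0.1
Cluster-24679.1	BAGP1	BAG-associated GRAM protein 1	37.1	74.0	3.7	0.0
Cluster-24856.0	C7A12	Cytochrome P450 CYP736A12	174.8	199.3	3.2	0.0
Cluster-25215.2	EP1L3	EP1-like glycoprotein 3	395.6	467.9	3.1	0.0
Cluster-25707.0	PMT1	Probable methyltransferase PMT1	28.0	67.0	5.1	0.0
Cluster-26296.0	RTNLB	Reticulon-like protein B2	226.7	269.3	9.2	0.1
Cluster-26397.0	RL24	60S ribosomal protein L24	56.8	102.6	3.8	0.0
Cluster-2641.0	VP371	Vacuolar protein-sorting-associated protein 37	104.5	151.3	11.6	0.0
Cluster-27486.3	KAD7	Probable adenylate kinase 7, mitochondrial	538.7	480.3	3.6	0.1
Cluster-28157.0	DG	DNA glycosylase superfamily protein	7.6	92.6	9.6	0.0
Cluster-28431.7	ALFC6	Fructose-bisphosphate aldolase 6, cytosolic	706.9	1620.3	3.6	0.0
Cluster-28487.3	ADS3	Palmitoyl-monogalactosyldiacylglycerol delta-7 desaturase	1432.6	1611.5	3.3	0.0
Cluster-30032.0	GRP	Glycine-rich protein A3	2030.6	2754.2	4.5	0.0
Cluster-31395.0	TRAPPC3	Transport protein particle (TRAPP)	95.3	98.7	10.1	0.0
Cluster-31481.0	CAMT	Caffeoyl-CoA O-methyltransferase	468.8	1485.6	5.5	0.0
Cluster-34709.1	IF5A	Eukaryotic translation initiation factor 5A	1030.8	908.8	3.1	0.0
Cluster-36607.0	PRU1	Major allergen Pru ar 1	2404.5	7930.2	8.7	0.3
Cluster-37697.0	TCTP	Translationally-controlled tumor protein	8294.9	9520.8	5.7	0.1
Cluster-4150.5	NIN1	Neutral/alkaline invertase 1, mitochondrial	195.7	202.0	3.8	0.0
Cluster-4583.0	PER52	Peroxidase 52	39.1	207.4	4.7	0.0
Cluster-6216.6	GBLP	Guanine nucleotide-binding protein subunit beta	147.5	161.5	5.6	0.0
Cluster-7222.7	GSTUP	Glutathione S-transferase U25	333.6	304.3	4.4	0.0
Cluster-7227.1	RS202	40S ribosomal protein	442.1	546.1	6.7	0.0
Cluster-7844.0	ZCF37	ZCF37 AT1G10220; IMPGSAL1N27970	56.3	70.4	3.2	0.0
Cluster-11481.5	G6PD	Glucose-6-phosphate 1-dehydrogenase	156.0	470.6	3.9	0.0
Cluster-13110.1	SD18	Receptor-like serine/threonine-protein kinase	73.9	94.1	13.7	0.0
Cluster-23641.1	XTH23	Xyloglucan endotransglucosylase/hydrolase protein 23	460.3	981.2	3.8	0.0
Cluster-25384.10	IPYR4	Soluble inorganic pyrophosphatase 4	458.4	438.7	3.4	0.0
Cluster-26866.5	ALA9	Phospholipid-transporting ATPase 9	72.1	32.5	6.7	0.0
Cluster-28356.0	CH62	Chaperonin CPN60-2, mitochondrial	205.4	149.5	3.7	0.0
Cluster-28583.0	PMTE	Methyltransferase PMT14	65.8	104.8	3.3	0.0
Cluster-29004.0	RS11	40S ribosomal protein S11	246.9	542.3	9.9	0.0
Cluster-29660.0	COPD	Coatomer subunit delta	110.9	159.9	3.0	0.0
Cluster-73329.0	EFTU	Elongation factor Tu, plastid	0.1	14.6	4.3	4.9
Cluster-83509.0	RL401	Ubiquitin-60S ribosomal protein	0.3	4.1	5.7	17.0
Cluster-86098.6	BiP	Luminal-binding protein	0.1	3.5	9.0	14.4
Cluster-43539.64	--	--	0.3	3.5	5.9	23.1
Cluster-92949.1	PAT	Glutamate/aspartate-prephenate aminotransferase	0.0	10.7	96.7	19.8
Cluster-26621.39	YCF68	Uncharacterized protein	0.7	65.8	18.8	3.4
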