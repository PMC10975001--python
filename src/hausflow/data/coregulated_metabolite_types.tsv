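compound	cas	category	type_TH_vs_THC	type_P_vs_PC
2,3,19-Trihydroxyurs-12-en-28-oic acid	-	Terpenoids	up	up
Pinfaensic acid	-	Terpenoids	up	up
N,N'-Dimethylarginine; SDMA	30344-00-4	Amino acids and derivatives	up	up
N-Monomethyl-L-arginine	17035-90-4	Amino acids and derivatives	up	up
L-Isoleucyl-L-Aspartate	-	Amino acids and derivatives	up	up
L-Aspartyl-L-Phenylalanine	13433-09-5	Amino acids and derivatives	up	up
Candelabrone 12-methyl ether	-	Terpenoids	up	up
19-Hydroxyursolic acid	-	Terpenoids	up	up
Homoarginine	156-86-5	Amino acids and derivatives	up	up
NG,NG-Dimethyl-L-arginine	30315-93-6	Amino acids and derivatives	up	up
2-Deoxyribose-1-phosphate	17210-42-3	Nucleotides and derivatives	up	up
6'-O-Feruloyl-D-sucrose	118230-77-6	Phenolic acids	up	up
Jasmonic acid	77026-92-7	Organic acids	up	up
2-Acetoxymethyl-anthraquinone	-	Quinones	up	up
Propyl 4-hydroxybenzoate	94-13-3	Phenolic acids	up	up
5-hydroxy-1-phenyl-7-3-heptanone	-	Others	up	up
2,2-Dimethylsuccinic acid	597-43-3	Organic acids	up	up
L-Tartaric acid	87-69-4	Organic acids	up	down
Tachioside	109194-60-7	Phenolic acids	down	down
Isotachioside	31427-08-4	Phenolic acids	down	down
1-O-Salicyloyl-beta-D-glucose	60517-74-0	Phenolic acids	down	down
Salicylic acid-2-O-glucoside	10366-91-3	Phenolic acids	down	down
p-Hydroxypheny-beta-D-allopyranoside	-	Phenolic acids	down	down
Arbutin	497-76-7	Phenolic acids	down	down
Sinapoyl malate	92344-58-6	Phenolic acids	down	down
2-O-Caffeoylglucaric Acid	-	Phenolic acids	down	down
Oleic acid	112-80-1	Lipids	down	down
N-Methyl-Trans-4-Hydroxy-L-Proline	4252-82-8	Amino acids and derivatives	down	down
2,6-Dimethoxy-4-hydroxyphenol-1-O-beta-D-glucopyranoside	-	Others	down	down
Methoxyindoleacetic acid	3471-31-6	Alkaloids	down	up
Tryptamine	61-54-1	Alkaloids	down	up
L-Tryptophan	73-22-3	Amino acids and derivatives	down	up
3-Indoleacetonitrile	771-51-7	Alkaloids	down	up
1-Methoxy-indole-3-acetamide	-	Alkaloids	down	up
Indole	120-72-9	Alkaloids	down	up
3-Indolepropionic acid	830-96-6	Alkaloids	down	up
3-Indoleacrylic acid	1204-06-4	Alkaloids	down	up
gamma-glutamylmethionine	17663-87-5	Amino acids and derivatives	down	up
2-Aminoethanesulfonic acid	107-35-7	Organic acids	down	up
p-Coumaric acid methyl ester	19367-38-5	Phenolic acids	down	up
Roseoside	54835-70-0	Others	down	up
Isoquinoline	119-65-3	Alkaloids	down	up
4-caffeoylshikimic acid	-	Phenolic acids	down	up
L-Histidine	71-00-1	Amino acids and derivatives	down	up
Phlorizin	60-81-1	Flavonoids	down	up
3,4-Methylenedioxy cinnamyl alcohol	58095-76-4	Lignans and Coumarins	down	up
Kaurenoic Acid	6730-83-2	Terpenoids	down	up
LysoPC 15:0	108273-89-8	Lipids	down	up
Melibiose	585-99-9	Others	down	up
3-amino-2-naphthoic acid	-	Alkaloids	down	up
L-Lysine-Butanoic Acid	80407-71-2	Amino acids and derivatives	down	up
cyclo-(Gly-Phe)	10125-07-2	Amino acids and derivatives	down	up
Trans-Citridic acid	4023-65-8	Organic acids	down	up
1-O-Sinapoyl-beta-D-glucose	-	Phenolic acids	down	up
Linarin	480-36-4	Flavonoids	down	up
Syringaresinol-4'-O-glucoside	7374-79-0	Lignans and Coumarins	down	up
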