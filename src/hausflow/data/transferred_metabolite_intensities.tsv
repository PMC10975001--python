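compound	category	TH	THC	PC	P
Ethylsalicylate	Phenolic acids	-	35397	500949	542212
Eriodictyol-7-O-glucoside	Flavonoids	-	29411	3851867	4694065
Aromadendrin-7-O-glucoside	Flavonoids	-	113418	1191540	604233
Pruvuloside B	Terpenoids	-	1789	54923	40759
2-Ethylpyrazine	Alkaloids	49686	43058	78849	-
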