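mz	rt	adduct	monoisotopic_mass	auc	tentative_id	n_other_hits	comparison	polarity
546.3528	14.59	[M+Na]+	523.3638	0.59	Platelet-activating factor	6	low_vs_high	positive
544.3373	13.35	[M+Na]+	521.3481	0.58	LysoPC(0:0/18:1(9Z))	5	low_vs_high	positive
116.0708	0.60	[M+H]+	115.0633	0.58	Proline	0	low_vs_high	positive
427.1938	5.74	[M+NH4]+	409.1584	0.58	dermatan L-iduronate	1	low_vs_high	positive
496.3397	12.95	[M+Na]+	473.3505	0.57	Clupanodonyl carnitine	5	low_vs_high	positive
373.2735	9.79	[M+H]+	372.2664	0.57	Cervonoyl ethanolamide	0	low_vs_high	positive
520.3398	12.33	[M+H]+	519.3325	0.57	LysoPC(0:0/18:2(9Z,12Z))	1	low_vs_high	positive
370.2950	8.20	[M+NH4]+	352.2614	0.57	MG(18:3(6Z,9Z,12Z)/0:0/0:0)	8	low_vs_high	positive
289.1409	5.12	[M+Na]+	266.1518	0.57	pentadeca-5,7,9-trienedioic acid	8	low_vs_high	positive
356.2793	7.49	[M+NH4]+	338.2457	0.57	11,12-DiHETrE	8	low_vs_high	positive
211.1441	3.90	[M+NH4]+	193.1103	0.60	(R)-N-Methylsalsolinol	3	moderate_vs_high	positive
215.1279	4.78	[M+H]+	214.1205	0.58	undec-3-enedioic acid	3	moderate_vs_high	positive
769.4224	21.08	[M+Na]+	746.4370	0.57	PG(20:4(8Z,11Z,14Z,17Z)-2OH(5S,6R)/i-12:0)	5	moderate_vs_high	positive
760.5845	20.22	[M+H]+	759.5778	0.57	Pe-NMe2(20:1(11Z)/15:0)	26	moderate_vs_high	positive
802.5350	19.32	[M+Na]+	779.5465	0.57	PC(20:5(6E,8Z,11Z,14Z,17Z)-OH(5)/P-16:0)	89	moderate_vs_high	positive
496.3397	12.95	[M+Na]+	473.3505	0.57	Clupanodonyl carnitine	5	moderate_vs_high	positive
544.3373	13.35	[M+Na]+	521.3481	0.56	LysoPC(18:1(9Z)/0:0)	5	moderate_vs_high	positive
518.3215	12.95	[M+Na]+	495.3325	0.56	LysoPC(16:0/0:0)	2	moderate_vs_high	positive
351.2504	12.67	[M+Na]+	328.2614	0.56	MG(0:0/16:1(9Z)/0:0)	1	moderate_vs_high	positive
828.5507	19.67	[M+Na]+	805.5621555	0.56	PC(20:5(6E,8Z,11Z,14Z,17Z)-OH(5)/P-18:1(9Z))	107	moderate_vs_high	positive
311.1464	3.40	[M+NH4]+	293.1111	0.75	4-Hydroxyproline galactoside	3	low_vs_moderate	positive
524.3710	14.21	[M+H]+	523.3638	0.72	Platelet-activating factor	4	low_vs_moderate	positive
263.0887	6.70	[M+Na]+	240.0998	0.72	3-Carboxy-4-methyl-5-propyl-2-furanpropionic acid	4	low_vs_moderate	positive
641.5110	20.65	[M+NH4]+	623.4761	0.71	Cer(d16:1/6 keto-PGF1alpha)	58	low_vs_moderate	positive
830.5664	19.88	[M+Na]+	807.5778	0.71	PC(20:4(5Z,7E,11Z,14Z)-OH(9)/P-18:1(9Z))	151	low_vs_moderate	positive
769.4224	21.08	[M+Na]+	746.4370	0.70	PG(i-12:0/20:4(6Z,8E,10E,14Z)-2OH(5S,12R))	5	low_vs_moderate	positive
188.0707	2.35	[M+H]+	187.0633	0.70	Indoleacrylic acid	0	low_vs_moderate	positive
813.6839	21.40	[M+H]+	812.6771	0.68	SM(d18:2(4E,14Z)/24:0)	1	low_vs_moderate	positive
377.2659	13.29	[M+Na]+	354.2770	0.68	Glyceryl monolinoleate	0	low_vs_moderate	positive
343.2241	11.17	[M+Na]+	320.2351	0.67	12-HETE	39	low_vs_moderate	positive
212.0026	3.97	[M-H]-	213.0096	0.72	Indoxyl sulfate	3	low_vs_moderate	negative
729.1788	11.02	[M+Cl]-	694.2109	0.69	Neocuscutoside C	3	low_vs_moderate	negative
464.3020	7.39	[M-H]-	465.3090	0.67	Glyco-beta-muricholic acid	5	low_vs_moderate	negative
802.5614	13.14	[M-H]-	803.5676	0.67	PE(PGF1alpha/P-18:0)	38	low_vs_moderate	negative
343.1707	8.15	[M-H]-	344.1776	0.64	Tamoxifen-ol	0	low_vs_moderate	negative
667.1419	11.98	[M-H]-	668.1506	0.63	Etoposide Phosphate	1	low_vs_moderate	negative
448.3073	8.18	[M-H]-	449.3141	0.63	Glycohyodeoxycholic acid	7	low_vs_moderate	negative
388.1559	8.00	[M+Cl]-	353.1852	0.63	Epiroprim	0	low_vs_moderate	negative
203.08299	3.58	[M-H]-	204.0899	0.63	L-Tryptophan	13	low_vs_moderate	negative
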