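name	monoisotopic_mass
Proline	115.0633
Indoleacrylic acid	187.0633
(R)-N-Methylsalsolinol	193.1103
L-Tryptophan	204.0899
Indoxyl sulfate	213.0096
undec-3-enedioic acid	214.1205
3-Carboxy-4-methyl-5-propyl-2-furanpropionic acid	240.0998
pentadeca-5,7,9-trienedioic acid	266.1518
4-Hydroxyproline galactoside	293.1111
12-HETE	320.2351
MG(0:0/16:1(9Z)/0:0)	328.2614
11,12-DiHETrE	338.2457
Tamoxifen-ol	344.1776
MG(18:3(6Z,9Z,12Z)/0:0/0:0)	352.2614
Epiroprim	353.1852
Glyceryl monolinoleate	354.277
Cervonoyl ethanolamide	372.2664
dermatan L-iduronate	409.1584
Glycohyodeoxycholic acid	449.3141
Glyco-beta-muricholic acid	465.309
Clupanodonyl carnitine	473.3505
LysoPC(16:0/0:0)	495.3325
LysoPC(0:0/18:2(9Z,12Z))	519.3325
LysoPC(18:1(9Z)/0:0)	521.3481
LysoPC(0:0/18:1(9Z))	521.3481
Platelet-activating factor	523.3638
Cer(d16:1/6 keto-PGF1alpha)	623.4761
Etoposide Phosphate	668.1506
Neocuscutoside C	694.2109
PG(20:4(8Z,11Z,14Z,17Z)-2OH(5S,6R)/i-12:0)	746.437
PG(i-12:0/20:4(6Z,8E,10E,14Z)-2OH(5S,12R))	746.437
Pe-NMe2(20:1(11Z)/15:0)	759.5778
PC(20:5(6E,8Z,11Z,14Z,17Z)-OH(5)/P-16:0)	779.5465
PE(PGF1alpha/P-18:0)	803.5676
PC(20:5(6E,8Z,11Z,14Z,17Z)-OH(5)/P-18:1(9Z))	805.5621555
PC(20:4(5Z,7E,11Z,14Z)-OH(9)/P-18:1(9Z))	807.5778
SM(d18:2(4E,14Z)/24:0)	812.6771
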