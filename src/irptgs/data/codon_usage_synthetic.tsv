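codon	amino_acid	frequency
TAA	*	0.2392
TAG	*	0.1818
TGA	*	0.5790
GCA	A	0.2359
GCC	A	0.4144
GCG	A	0.0049
GCT	A	0.3449
TGC	C	0.6562
TGT	C	0.3438
GAC	D	0.8266
GAT	D	0.1734
GAA	E	0.9646
GAG	E	0.0354
TTC	F	0.3658
TTT	F	0.6342
GGA	G	0.1217
GGC	G	0.0968
GGG	G	0.4261
GGT	G	0.3554
CAC	H	0.3893
CAT	H	0.6107
ATA	I	0.3891
ATC	I	0.3248
ATT	I	0.2861
AAA	K	0.2317
AAG	K	0.7683
CTA	L	0.0059
CTC	L	0.1237
CTG	L	0.1530
CTT	L	0.0619
TTA	L	0.4323
TTG	L	0.2233
ATG	M	1.0000
AAC	N	0.4850
AAT	N	0.5150
CCA	P	0.3040
CCC	P	0.4724
CCG	P	0.0958
CCT	P	0.1278
CAA	Q	0.6953
CAG	Q	0.3047
AGA	R	0.1927
AGG	R	0.0166
CGA	R	0.1220
CGC	R	0.0789
CGG	R	0.1516
CGT	R	0.4382
AGC	S	0.1127
AGT	S	0.2561
TCA	S	0.3937
TCC	S	0.0141
TCG	S	0.1062
TCT	S	0.1171
ACA	T	0.1038
ACC	T	0.3109
ACG	T	0.0148
ACT	T	0.5705
GTA	V	0.1102
GTC	V	0.0728
GTG	V	0.4903
GTT	V	0.3266
TGG	W	1.0000
TAC	Y	0.0598
TAT	Y	0.9402
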