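codon	aa	count	rscu
UUU	F	251	1.63
UUC	F	57	0.37
UUA	L	250	2.46
UUG	L	80	0.79
CUU	L	123	1.21
CUC	L	33	0.32
CUA	L	99	0.97
CUG	L	25	0.25
AUU	I	218	1.53
AUC	I	67	0.47
AUA	M	139	1.51
AUG	M	45	0.49
GUU	V	113	1.74
GUC	V	21	0.32
GUA	V	92	1.42
GUG	V	34	0.52
UCU	S	116	2.68
UCC	S	20	0.46
UCA	S	55	1.27
UCG	S	5	0.12
CCU	P	52	1.40
CCC	P	50	1.34
CCA	P	41	1.10
CCG	P	6	0.16
ACU	T	96	1.84
ACC	T	44	0.84
ACA	T	61	1.17
ACG	T	8	0.15
GCU	A	108	1.70
GCC	A	73	1.15
GCA	A	57	0.90
GCG	A	16	0.25
UAU	Y	74	1.21
UAC	Y	48	0.79
UAA	*	8	1.33
UAG	*	4	0.67
CAU	H	31	0.81
CAC	H	46	1.19
CAA	Q	55	1.49
CAG	Q	19	0.51
AAU	N	69	1.11
AAC	N	55	0.89
AAA	K	69	1.60
AAG	K	17	0.40
GAU	D	42	1.25
GAC	D	25	0.75
GAA	E	51	1.23
GAG	E	32	0.77
UGU	C	34	1.36
UGC	C	16	0.64
UGA	W	77	1.50
UGG	W	26	0.50
CGU	R	11	0.70
CGC	R	7	0.44
CGA	R	37	2.35
CGG	R	8	0.51
AGU	S	36	0.83
AGC	S	22	0.51
AGA	S	61	1.41
AGG	S	31	0.72
GGU	G	38	0.59
GGC	G	43	0.67
GGA	G	102	1.59
GGG	G	73	1.14
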