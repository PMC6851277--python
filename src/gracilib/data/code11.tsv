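# NCBI translation table 11 (Bacterial)
codon	aa	is_start
TTT	F	0
TTC	F	0
TTA	L	0
TTG	L	1
TCT	S	0
TCC	S	0
TCA	S	0
TCG	S	0
TAT	Y	0
TAC	Y	0
TAA	*	0
TAG	*	0
TGT	C	0
TGC	C	0
TGA	*	0
TGG	W	0
CTT	L	0
CTC	L	0
CTA	L	0
CTG	L	1
CCT	P	0
CCC	P	0
CCA	P	0
CCG	P	0
CAT	H	0
CAC	H	0
CAA	Q	0
CAG	Q	0
CGT	R	0
CGC	R	0
CGA	R	0
CGG	R	0
ATT	I	1
ATC	I	1
ATA	I	1
ATG	M	1
ACT	T	0
ACC	T	0
ACA	T	0
ACG	T	0
AAT	N	0
AAC	N	0
AAA	K	0
AAG	K	0
AGT	S	0
AGC	S	0
AGA	R	0
AGG	R	0
GTT	V	0
GTC	V	0
GTA	V	0
GTG	V	1
GCT	A	0
GCC	A	0
GCA	A	0
GCG	A	0
GAT	D	0
GAC	D	0
GAA	E	0
GAG	E	0
GGT	G	0
GGC	G	0
GGA	G	0
GGG	G	0
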