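three	one	name	extended
Ala	A	Alanine	0
Arg	R	Arginine	0
Asn	N	Asparagine	0
Asp	D	Aspartate	0
Cys	C	Cysteine	0
Gln	Q	Glutamine	0
Glu	E	Glutamate	0
Gly	G	Glycine	0
His	H	Histidine	0
Ile	I	Isoleucine	0
Leu	L	Leucine	0
Lys	K	Lysine	0
Met	M	Methionine	0
Phe	F	Phenylalanine	0
Pro	P	Proline	0
Ser	S	Serine	0
Thr	T	Threonine	0
Trp	W	Tryptophan	0
Tyr	Y	Tyrosine	0
Val	V	Valine	0
Sec	U	Selenocysteine	1
Pyl	O	Pyrrolysine	1
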