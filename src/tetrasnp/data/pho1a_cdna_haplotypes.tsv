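position	amino_acid_change	1	2	3	4	5	6	7	8	9
22	His8Tyr	C	T	T	T	T	T	C	C	C
322	Ala108Thr	G	A	A	A	A	A	G	G	G
504	-	C	C	C	C	C	C	T	T	T
534	-	A	G	G	G	G	G	G	G	G
720	-	A	C	C	C	C	C	A	A	A
824	Lys275Arg	A	A	A	G	G	G	A	A	A
1923	-	G	G	G	G	T	T	G	G	G
1939	Ala647Ser	G	G	G	G	T	T	G	G	G
2578	Gly860Arg	G	G	G	G	G	G	A	A	A
2616	-	G	G	G	G	G	G	G	G	A
2754	-	G	G	G	G	G	G	A	A	G
2765	Glu922Val	A	A	A	A	A	A	A	A	T
2776	Asp926Asn	G	G	A	G	A	G	G	G	G
2795	Thr923Lys	C	A	A	C	A	A	A	A	A
2823	-	G	C	C	G	C	C	C	G	G
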