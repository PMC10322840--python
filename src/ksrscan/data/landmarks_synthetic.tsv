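sequence_id	landmark	position	residue
BRAF	S446	446	S
BRAF	D449	449	D
BRAF	G464	464	G
BRAF	G466	466	G
BRAF	F468	468	F
BRAF	G469	469	G
BRAF	K483	483	K
BRAF	L485	485	L
BRAF	V487	487	V
BRAF	Q493	493	Q
BRAF	A496	496	A
BRAF	F497	497	F
BRAF	K499	499	K
BRAF	L505	505	L
BRAF	R506	506	R
BRAF	T508	508	T
BRAF	R509	509	R
BRAF	D576	576	D
BRAF	D587	587	D
BRAF	L588	588	L
BRAF	D594	594	D
BRAF	L597	597	L
BRAF	T599	599	T
BRAF	V600	600	V
KSR1	R608	608	R
KSR3_PL	C37	37	C
KSR3_PL	C40	40	C
KSR3_PL	S84	84	S
KSR3_PL	S87	87	S
KSR3_PL	S306	306	S
KSR3_PL	E307	307	E
KSR3_PL	R343	343	R
KSR3_PL	L354	354	L
KSR3_PL	S361	361	S
KSR3_PL	K362	362	K
KSR3_PL	I363	363	I
KSR3_PL	R364	364	R
KSR3_PL	K443	443	K
KSR3_PL	V444	444	V
KSR3_PL	D452	452	D
KSR3_PL	D455	455	D
KSR3_PL	S586	586	S
KSR3_SK	C37	37	C
KSR3_SK	C40	40	C
KSR3_SK	S84	84	S
KSR3_SK	S87	87	S
KSR3_SK	D293	293	D
KSR3_SK	E294	294	E
KSR3_SK	R350	350	R
KSR3_SK	S572	572	S
KSR3_NV	R390	390	R
KSR3_NV	S618	618	S
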