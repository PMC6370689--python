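group	subclass	site1	site2	site3	site4	site5	site6	site7	site8
NrdBe	Ia	D	E	H	E	E	H	I/M/V	D
NrdBg	Ia	D	E	H	E	E	H	S	D
NrdBh	Ia_presumed	D	E	H	E	E	H	E/Q	D
NrdBk	Ia_presumed	D	E	H	E	E	H	I/M/R	D/E
NrdBn	Ia_presumed	D	E	H	E	E	H	E	D
NrdBza	Ia_presumed	D	E	H	E	E	H	E	D
NrdFb	Ib	D	E	H	E	E	H	M	D
NrdBzc	Ic	E	E	H	E	E	H	E	D
NrdBi	Id	E	E	H	E	E	H	C/S	D/E
NrdFe	Ie	D	Q/V	H	P/S	K	H	M	D
CyanoSP	If	E	E	H	E	E	H	D	D
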