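# Bond-valence parameters r0 (Angstrom) for ion-donor pairs, softness b (Angstrom).
# Values from the Brown & Altermatt (1985) and Brese & O'Keeffe (1991) compilations
# for the divalent/monovalent oxidation states relevant to biological crystallography.
# ion	donor	r0	b	source
NA	O	1.803	0.37	Brown & Altermatt (1985)
NA	N	1.930	0.37	Brese & O'Keeffe (1991)
NA	CL	2.150	0.37	Brese & O'Keeffe (1991)
MG	O	1.693	0.37	Brown & Altermatt (1985)
MG	N	1.850	0.37	Brese & O'Keeffe (1991)
MG	CL	2.080	0.37	Brese & O'Keeffe (1991)
K	O	2.132	0.37	Brown & Altermatt (1985)
K	N	2.260	0.37	Brese & O'Keeffe (1991)
K	CL	2.519	0.37	Brese & O'Keeffe (1991)
CA	O	1.967	0.37	Brown & Altermatt (1985)
CA	N	2.140	0.37	Brese & O'Keeffe (1991)
CA	CL	2.370	0.37	Brese & O'Keeffe (1991)
MN	O	1.790	0.37	Brown & Altermatt (1985), Mn(II)
MN	N	1.849	0.37	Brese & O'Keeffe (1991), Mn(II)
MN	S	2.220	0.37	Brese & O'Keeffe (1991), Mn(II)
MN	CL	2.133	0.37	Brown & Altermatt (1985), Mn(II)
FE	O	1.734	0.37	Brown & Altermatt (1985), Fe(II)
FE	N	1.769	0.37	Brese & O'Keeffe (1991), Fe(II)
FE	S	2.125	0.37	Brese & O'Keeffe (1991), Fe(II)
FE	CL	2.060	0.37	Brown & Altermatt (1985), Fe(II)
CO	O	1.692	0.37	Brown & Altermatt (1985), Co(II)
CO	N	1.720	0.37	Brese & O'Keeffe (1991), Co(II)
CO	S	2.060	0.37	Brese & O'Keeffe (1991), Co(II)
CO	CL	2.010	0.37	Brese & O'Keeffe (1991), Co(II)
NI	O	1.654	0.37	Brown & Altermatt (1985), Ni(II)
NI	N	1.700	0.37	Brese & O'Keeffe (1991), Ni(II)
NI	S	1.940	0.37	Brese & O'Keeffe (1991), Ni(II)
NI	CL	2.020	0.37	Brese & O'Keeffe (1991), Ni(II)
CU	O	1.679	0.37	Brown & Altermatt (1985), Cu(II)
CU	N	1.751	0.37	Brese & O'Keeffe (1991), Cu(II)
CU	S	2.050	0.37	Brese & O'Keeffe (1991), Cu(II)
CU	CL	2.000	0.37	Brese & O'Keeffe (1991), Cu(II)
ZN	O	1.704	0.37	Brown & Altermatt (1985)
ZN	N	1.770	0.37	Brese & O'Keeffe (1991)
ZN	S	2.090	0.37	Brese & O'Keeffe (1991)
ZN	CL	2.010	0.37	Brown & Altermatt (1985)
CD	O	1.904	0.37	Brown & Altermatt (1985)
CD	N	2.140	0.37	Brese & O'Keeffe (1991)
CD	S	2.304	0.37	Brese & O'Keeffe (1991)
CD	CL	2.230	0.37	Brown & Altermatt (1985)
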