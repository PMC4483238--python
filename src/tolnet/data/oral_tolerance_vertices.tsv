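id	label	component_class	is_source
1	Antigen	antigen	1
2	sIgA	molecular	0
3	sIgG	molecular	0
4	FcRn	cellular	0
5	Enterocyte	cellular	0
6	Tight junction	cellular	0
7	Transcelular route	cellular	0
8	MHC II	cellular	0
9	M Cells	cellular	0
10	Goblet Cells	cellular	0
11	CX3CR1 Macrages	cellular	0
12	pDCs	cellular	0
13	CD103+	cellular	0
14	CD11b+	cellular	0
15	CD11c+	cellular	0
16	CCR7	cellular	0
17	CD3+	cellular	0
18	naive CD4FoxP3-	cellular	0
19	iTregFoxP3+	cellular	0
20	naturalTregFoxP3+	cellular	0
21	Tr1	cellular	0
22	Th3	cellular	0
23	B Cells	cellular	0
24	TGF-B	molecular	0
25	RA	molecular	0
26	IL-10	molecular	0
27	IL-27	molecular	0
28	IL-2	molecular	0
29	INF-lambda	molecular	0
30	CCL25	molecular	0
31	alpha-4-beta-7 integrin	cellular	0
32	CCR9	cellular	0
33	MadCAM-1	cellular	0
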