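# Oral-tolerance interaction network, hand-transcribed edge list.
# Two columns: source_label <TAB> target_label. See oral_tolerance_manifest.json
# for the per-edge provenance and transcription caveats.
Antigen	sIgG
Antigen	sIgA
Antigen	Enterocyte
Antigen	Tight junction
Antigen	M Cells
Antigen	Goblet Cells
Antigen	CX3CR1 Macrages
Antigen	pDCs
sIgG	FcRn
sIgG	Enterocyte
sIgA	M Cells
sIgA	Enterocyte
FcRn	CD103+
FcRn	Enterocyte
Enterocyte	Transcelular route
Enterocyte	MHC II
Tight junction	CD103+
Tight junction	CX3CR1 Macrages
Transcelular route	CD103+
Transcelular route	CX3CR1 Macrages
MHC II	CD103+
MHC II	CX3CR1 Macrages
M Cells	CD11b+
M Cells	CD11c+
Goblet Cells	CD103+
Goblet Cells	CD11c+
CX3CR1 Macrages	CD103+
CX3CR1 Macrages	IL-10
pDCs	IL-27
pDCs	INF-lambda
CD103+	CCR7
CD103+	TGF-B
CD103+	RA
CD103+	IL-10
CD103+	CD3+
CCR7	naive CD4FoxP3-
CCR7	CD3+
CD3+	naive CD4FoxP3-
CD3+	IL-2
CD3+	naturalTregFoxP3+
naive CD4FoxP3-	iTregFoxP3+
naive CD4FoxP3-	Tr1
naive CD4FoxP3-	Th3
naive CD4FoxP3-	B Cells
TGF-B	iTregFoxP3+
TGF-B	Th3
TGF-B	B Cells
TGF-B	Enterocyte
TGF-B	Tight junction
RA	alpha-4-beta-7 integrin
RA	CCR9
RA	iTregFoxP3+
alpha-4-beta-7 integrin	MadCAM-1
alpha-4-beta-7 integrin	iTregFoxP3+
CCR9	CCL25
CCR9	iTregFoxP3+
MadCAM-1	iTregFoxP3+
MadCAM-1	naturalTregFoxP3+
CCL25	iTregFoxP3+
CCL25	pDCs
iTregFoxP3+	TGF-B
iTregFoxP3+	IL-10
iTregFoxP3+	CD11b+
CD11b+	IL-27
CD11b+	IL-10
IL-27	Tr1
IL-27	IL-10
Tr1	IL-10
Tr1	TGF-B
IL-10	iTregFoxP3+
IL-10	Tr1
IL-10	CX3CR1 Macrages
Th3	TGF-B
Th3	IL-10
naturalTregFoxP3+	IL-10
naturalTregFoxP3+	TGF-B
IL-2	iTregFoxP3+
IL-2	naturalTregFoxP3+
B Cells	sIgA
B Cells	sIgG
INF-lambda	Enterocyte
INF-lambda	Goblet Cells
CD11c+	naive CD4FoxP3-
CD11c+	IL-10
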