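mechanical_axis	curated cytoskeletal-nuclear mechanical axis, 55 genes (reconstruction: named families expanded to HGNC symbols)	LMNA	LMNB1	LMNB2	ACTB	ACTG1	TUBA1A	TUBB	SYNE1	SYNE2	SYNE3	SYNE4	SUN1	SUN2	EMD	NUP35	NUP37	NUP43	NUP50	NUP54	NUP58	NUP62	NUP85	NUP88	NUP93	NUP98	NUP107	NUP133	NUP153	NUP155	NUP160	NUP188	NUP205	NUP210	NUP214	RANBP2	POM121	POM121C	TPR	NUPL1	RAE1	IPO4	IPO5	IPO7	IPO8	IPO9	IPO11	IPO13	NXF1	RAN	RANBP1	RCC1	HSPA8	VIM	UBE2I	SENP2
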