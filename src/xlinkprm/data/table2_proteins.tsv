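id	name_1	mw_1	gene_1	uniprot_1	name_2	mw_2	gene_2	uniprot_2
1	Src kinase-associated phosphoprotein 2	41.2	SKAP2	O75563	Src kinase-associated phosphoprotein 2	42.2	SKAP2	O75563
2	Myosin-9	226.5	MYH9	P35579	Myosin-9	226.5	MYH9	P35579
3	Talin-1	269.8	TLN1	Q9Y490	Talin-1	269.8	TLN1	Q9Y490
4	Myosin-9	226.5	MYH9	P35579	Myosin-9	226.5	MYH9	P35579
5	Keratin	66	KRT1	P04264	Keratin	66	KRT1	P04264
6	Albumin	69.4	ALB	P02768	Albumin	69.4	ALB	P02768
7	POTE ankyrin domain family member F/Actin	121.4/41.9	POTEF/ACTG2	A5A3E0/P63267	Actin	41.9	ACTG2	P63267
8	POTE ankyrin domain family member F/Actin	121.4/41.9	POTEF/ACTG2	A5A3E0/P63267	Actin	41.9	ACTG2	P63267
9	Mannosyl-oligosaccharide glucosidase	91.9	MOGS	Q13724	Histone H2B	13.9	H2BC12	O60814
10	Transaldolase	37.5	TALDO1	P37837	Transaldolase	37.5	TALDO1	P37837
11	Catalase	59.8	CAT	P04040	Catalase	59.8	CAT	P04040
12	Histone H4	11.4	H4C1-16	P62805	Histone H2B	13.9	H2BC12	O60814
13	Histone H4	11.4	H4C1-16	P62805	Histone H2B	13.9	H2BC12	O60814
14	Potassium voltage-gated channel subfamily H member 8	123.8	KCNH8	Q96L42	Nexilin	80.7	NEXN	Q0ZGT2
15	Arf-GAP with SH3 domain, ANK repeat and PH domain-containing protein 2	111.7	ASAP2	O43150	Myosin-9	226.5	MYH9	P35579
16	Multiple epidermal growth-factor-like domain protein 11	110.8	MEGF11	A6BM72	Multiple epidermal growth factor-like domain protein 11	110.8	MEGF11	A6BM72
17	GRIP and coiled-coil domain-containing protein 1	87.8	GCC1	Q96CN9	Nexilin	80.7	NEXN	Q0ZGT2
18	Docking protein 2	45.4	DOK2	O60496	Albumin	69.4	ALB	P02768
19	Albumin	69.4	ALB	P02768	Albumin	69.4	ALB	P02768
20	Lactotransferrin	78.2	LTF	P02788	Lactotransferrin	78.2	LTF	P02788
21	Lactotransferrin	78.2	LTF	P02788	Integral membrane protein 2B	30.3	ITM2B	Q9Y287
22	Albumin	69.4	ALB	P02768	Albumin	69.4	ALB	P02768
23	Histone H2B	13.9	H2BC12	O60814	AFG3-like protein 2	88.6	AFG3L2	Q9Y4W6
24	Histone H2B	13.9	H2BC12	O60814	Histone H4	11.4	H4C1-16	P62805
25	Histone H2B	13.9	H2BC12	O60814	Histone H4	11.4	H4C1-16	P62805
26	Olfactory receptor 10J4	34.9	OR10J4	P0C629	Indian hedgehog protein	45.25	IHH	Q14623
27	Histone H2B	13.9	H2BC12	O60814	Histone H4	11.4	H4C1-16	P62805
28	Myosin light chain kinase	210.7	MYLK	Q15746	Albumin	69.4	ALB	P02768
29	Protein S100-A8	10.8	S100A8	P05109	Protein S100-A8	10.8	S100A8	P05109
30	Protein S100-A8	10.8	S100A8	P05109	Protein S100-A8	10.8	S100A8	P05109
31	Albumin	69.4	ALB	P02768	DNA repair protein RAD50	153.9	RAD50	Q92878
32	Lactotransferrin	78.2	LTF	P02788	Lactotransferrin	78.2	LTF	P02788
33	Adenylyl cyclase-associated protein 1	51.9	CAP1	Q01518	Protein S100-A8	10.8	S100A8	P05109
34	Protein S100-A8	10.8	S100A8	P05109	Protein S100-A8	10.8	S100A8	P05109
35	Protein mono-ADP-ribosyltransferase PARP9	96.3	PARP9	Q8IXQ6	Myosin-9	226.5	MYH9	P35579
36	Lactotransferrin	78.2	LTF	P02788	Lactotransferrin	78.2	LTF	P02788
37	Myeloid cell nuclear differentiation antigen	45.8	MNDA	P41218	Myeloid cell nuclear differentiation antigen	45.8	MNDA	P41218
38	Histone H2B	13.9	H2BC12	O60814	Histone H4	11.4	H4C1-16	P62805
39	Protein S100-A8	10.8	S100A8	P05109	Protein S100-A8	10.8	S100A8	P05109
40	Protein S100-A8	10.8	S100A8	P05109	Protein S100-A8	10.8	S100A8	P05109
41	Fibrinogen beta chain	55.9	FGB	P02675	Fibrinogen gamma chain	51.5	FGG	P02679
42	DnaJ homolog subfamily C member 13	254.4	DNAJC13	O75165	Histone H2B	13.9	H2BC12	O60814
43	Inositol 1,4,5-trisphosphate receptor type 1	313.9	ITPR1	Q14643	Albumin	69.4	ALB	P02768
44	Low-density lipoprotein receptor-related protein 11	53.3	LRP11	Q86VZ4	Ras-related protein Rab-33A	26.6	RAB33A	Q14088
45	Hemoglobin subunit delta	16.1	HBD	P02042	Hemoglobin subunit beta	16	HBB	P68871
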