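# Chinese cabbage VQ gene catalogue: locus, chromosome, strand, genomic span, CDS
# length, and the published derived protein properties (aa length, kDa, pI).
# Location cells keep the published digit grouping verbatim (four cells carry
# misplaced thousands separators); readers strip separators before parsing.
gene_name	locus_id	chrom	strand	location	cds_length	aa_printed	mw_kda_printed	pi_printed
BrVQ1-1	Bra025998	A06	-	6,588,703–6,588,999	297	98	10.81	4.75
BrVQ1-2	Bra016616	A08	+	19,301,503–19,301,796	294	97	10.92	5.13
BrVQ3-1	Bra025892	A06	-	8,759,573–8,760,265	693	230	25.07	8.67
BrVQ3-2	Bra012276	A07	+	8,889,633–8,890,172	540	179	19.29	5.1
BrVQ4	Bra030082	A07	+	6,712,561–6,713,295	735	244	26.74	9.66
BrVQ5	Bra035492	A08	-	7,791,236–7,791,901	666	221	25.40	6.58
BrVQ8	Bra033934	A02	-	108,00,121–10,800,534	414	137	15.36	10.19
BrVQ9-1	Bra035028	A07	-	21,850,607–21,851,491	885	294	31.58	10.12
BrVQ9-2	Bra008356	A02	-	14,998,946–14,999,815	870	289	31.19	10.39
BrVQ10-1	Bra008359	A02	+	15,035,463–15,035,777	315	104	11.61	5.83
BrVQ10-2	Bra003642	A07	-	14,203,152–14,203,469	318	105	11.69	5.01
BrVQ10-3	Bra035035	A07	+	21,882,989–21,883,270	282	93	10.44	4.67
BrVQ11-1	Bra035182	A07	+	22,479,008–22,479,511	504	167	18.96	7.96
BrVQ11-2	Bra003566	A07	-	13,824,994–13,825,515	522	173	19.66	9.69
BrVQ11-3	Bra008473	A02	+	15,858,716–15,859,210	495	164	18.79	8.74
BrVQ12	Bra039937	A09	+	31,714,821–31,715,237	417	138	16.09	9.66
BrVQ14-1	Bra023004	A03	+	8,183,495–8,184,808	1314	437	48.10	8.58
BrVQ14-2	Bra017329	A04	+	15,346,657–15,347,685	1029	342	37.24	10.53
BrVQ14-3	Bra005358	A05	-	5,012,814–5,014,478	1185	394	43.13	10.09
BrVQ15	Bra016956	A04	-	17,404,492–17,405,181	690	229	24.84	7.87
BrVQ16-1	Bra000216	A03	+	9,940,673–9,941,098	426	141	15.57	8.91
BrVQ16-2	Bra004604	A05	+	1,001,763–1,002,185	423	140	15.29	4.89
BrVQ18-1	Bra004825	A05	+	1,984,033–1,984,575	543	180	20.11	9.24
BrVQ18-2	Bra037658	A04	+	18,293,805–18,294,347	543	180	19.98	9.33
BrVQ19-1	Bra027262	A05	+	20,006,387–20,007,064	678	225	24.21	9.44
BrVQ19-2	Bra021096	A01	+	23,997,911–23,998,561	651	216	23.49	9.33
BrVQ20	Bra037588	A01	+	22,145,216–22,146,079	864	287	30.28	6.54
BrVQ21-1	Bra037569	A01	+	22,005,523–22,006,176	654	217	22.73	6.05
BrVQ21-2	Bra022345	A05	+	182,87,618–18,288,268	651	216	23.06	6.29
BrVQ21-3	Bra001716	A03	-	18,018,055–18,018,699	645	214	22.95	6.22
BrVQ22-1	Bra023849	A01	+	2,0411,389–20,411,979	591	196	20.61	9.69
BrVQ22-2	Bra041035	Scaffold000402	-	11,806–12,390	585	194	20.40	9.89
BrVQ23-1	Bra007265	A09	-	28,278,350–28,278,799	450	149	16.52	4.88
BrVQ23-2	Bra014675	A04	+	2,158,610–2,159,095	486	161	18.10	5.1
BrVQ23-3	Bra014674	A04	+	2,155,783–2,156,247	465	154	17.35	5.17
BrVQ24-1	Bra007279	A09	+	28,339,520–28,340,206	687	228	23.79	6.59
BrVQ24-2	Bra014665	A04	-	2,098,440–2,099,141	702	233	24.57	8.05
BrVQ25-1	Bra007373	A09	+	28,879,454–28,879,999	546	181	20.12	6.19
BrVQ25-2	Bra014594	A04	-	1,651,117–1,651,650	534	177	19.56	6.7
BrVQ26-1	Bra007505	A09	+	29,533,410–29,533,874	465	154	17.58	7.02
BrVQ26-2	Bra014514	A04	-	1,142,901–1,143,341	441	146	16.68	8
BrVQ26-3	Bra003400	A07	+	13,026,327–13,029,056	846	281	32.87	7.16
BrVQ27	Bra039565	A01	-	11,929,165–11,929,719	555	184	19.83	9.76
BrVQ28	Bra013438	A01	+	5,666,359–5,666,979	621	206	23.15	5.37
BrVQ29-1	Bra010608	A08	+	15,506,771–15,507,115	345	114	12.72	9.05
BrVQ29-2	Bra017849	A03	+	30,916,676–30,917,020	345	114	12.84	9.05
BrVQ30-1	Bra010666	A08	+	15,875,832–15,876,719	888	295	32.18	6.18
BrVQ30-2	Bra011838	A01	-	282,249–283,121	873	290	31.74	7.94
BrVQ31	Bra005995	A03	+	1,534,982–153,5506	525	174	19.11	9.37
BrVQ32-1	Bra022063	A02	+	18,984,720–18,985,412	693	230	25.41	10.26
BrVQ32-2	Bra024996	A06	-	24,596,158–24,596,844	687	228	25.12	9.99
BrVQ33-1	Bra003032	A10	+	5,893,364–5,894,047	684	227	25.28	9.99
BrVQ33-2	Bra022675	A02	-	8,093,063–8,093,788	726	241	26.93	9.75
BrVQ34-1	Bra024362	A06	+	15,221,647–15,222,738	1092	363	39.11	5.76
BrVQ34-2	Bra037806	A09	+	3,657,352–3,658,311	960	319	34.26	5.94
BrVQ34-3	Bra031876	A02	+	27,356,488–27,357,465	978	325	35.03	6.65
BrVQ35	Bra006328	A03	-	3,034,196–3,038,533	1707	568	62.99	8.89
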