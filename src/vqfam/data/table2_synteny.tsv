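# Synteny of Chinese cabbage VQ genes with Arabidopsis in the tPCK ancestral
# frame: one row per member gene with its subgenome (LF / MF1 / MF2).
# Genes without an Arabidopsis anchor have an empty ref_locus (and, where the
# source gives none, empty block/tpck_chrom).
block	tpck_chrom	ref_locus	gene_name	subgenome
A	tPCK1	AtVQ1 (AT1G17147)	BrVQ1-1	LF
A	tPCK1	AtVQ1 (AT1G17147)	BrVQ1-2	MF1
		 	BrVQ3-1	LF
		 	BrVQ3-2	MF2
B	tPCK1	AtVQ4 (AT1G28280)	BrVQ4	MF2
B	tPCK1	AtVQ5 (AT1G32585)	BrVQ5	MF1
E	tPCK6	AtVQ8 (AT1G68450)	BrVQ8	MF1
E	tPCK6	AtVQ9 (AT1G78310)	BrVQ9-1	LF
E	tPCK6	AtVQ9 (AT1G78310)	BrVQ9-2	MF1
E	tPCK6	AtVQ10 (AT1G78410)	BrVQ10-3	LF
E	tPCK6	AtVQ10 (AT1G78410)	BrVQ10-1	MF1
E	tPCK6	AtVQ10 (AT1G78410)	BrVQ10-2	MF2
E	tPCK6	AtVQ11 (AT1G80450)	BrVQ11-1	LF
E	tPCK6	AtVQ11 (AT1G80450)	BrVQ11-3	MF1
E	tPCK6	AtVQ11 (AT1G80450)	BrVQ11-2	MF2
I	tPCK3	AtVQ12 (AT2G22880)	BrVQ12	LF
J	tPCK3	AtVQ14 (AT2G35230)	BrVQ14-3	LF
J	tPCK3	AtVQ14 (AT2G35230)	BrVQ14-2	MF1
J	tPCK3	AtVQ14 (AT2G35230)	BrVQ14-1	MF2
J	tPCK3	AtVQ15 (AT2G41010)	BrVQ15	MF1
J	tPCK3	AtVQ16 (AT2G41180)	BrVQ16-2	LF
J	tPCK3	AtVQ16 (AT2G41180)	BrVQ16-1	MF2
J	tPCK3	AtVQ18 (AT2G44340)	BrVQ18-1	LF
J	tPCK3	AtVQ18 (AT2G44340)	BrVQ18-2	MF1
F	tPCK2	AtVQ19 (AT3G15300)	BrVQ19-1	LF
F	tPCK2	AtVQ19 (AT3G15300)	BrVQ19-2	MF1
F	tPCK2	AtVQ20 (AT3G18360)	BrVQ20	MF1
F	tPCK2	AtVQ21 (AT3G18690)	BrVQ21-2	LF
F	tPCK2	AtVQ21 (AT3G18690)	BrVQ21-1	MF1
F	tPCK2	AtVQ21 (AT3G18690)	BrVQ21-3	MF2
F	tPCK2	AtVQ22 (AT3G22160)	BrVQ22-1	MF1
N	tPCK6	AtVQ23 (AT3G56710)	BrVQ23-1	LF
N	tPCK6	AtVQ23 (AT3G56710)	BrVQ23-2	MF1
N	tPCK6	AtVQ23 (AT3G56710)	BrVQ23-3	MF1
N	tPCK6	AtVQ24 (AT3G56880)	BrVQ24-1	LF
N	tPCK6	AtVQ24 (AT3G56880)	BrVQ24-2	MF1
N	tPCK6	AtVQ25 (AT3G58000)	BrVQ25-1	LF
N	tPCK6	AtVQ25 (AT3G58000)	BrVQ25-2	MF1
N	tPCK6	AtVQ26 (AT3G60090)	BrVQ26-1	LF
N	tPCK6	AtVQ26 (AT3G60090)	BrVQ26-2	MF1
N	tPCK6	AtVQ26 (AT3G60090)	BrVQ26-3	MF2
T	tPCK4	AtVQ27 (AT4G15120)	BrVQ27	LF
U	tPCK4	AtVQ28 (AT4G20000)	BrVQ28	LF
U	tPCK4	AtVQ29 (AT4G37710)	BrVQ29-2	MF1
U	tPCK4	AtVQ29 (AT4G37710)	BrVQ29-1	MF2
U	tPCK4	AtVQ30 (AT4G39720)	BrVQ30-2	LF
U	tPCK4	AtVQ30 (AT4G39720)	BrVQ30-1	MF2
R	tPCK5	AtVQ31 (AT5G08480)	BrVQ31	MF1
V	tPCK7	AtVQ32 (AT5G46780)	BrVQ32-2	LF
V	tPCK7	AtVQ32 (AT5G46780)	BrVQ32-1	MF1
Wb	tPCK5	AtVQ33 (AT5G53830)	BrVQ33-1	LF
Wb	tPCK5	AtVQ33 (AT5G53830)	BrVQ33-2	MF2
X	tPCK7	AtVQ34 (AT5G65170)	BrVQ34-1	LF
X	tPCK7	AtVQ34 (AT5G65170)	BrVQ34-3	MF1
X	tPCK7	AtVQ34 (AT5G65170)	BrVQ34-2	MF2
		 	BrVQ35	MF1
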