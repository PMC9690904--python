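# episig-table-v1: Clark-Baraitser syndrome (TRIP12) case cohort, transcribed from the published molecular table
id	sex	age	variant	origin	test	variant_class	cohort_role
1	F	49	c.1921C>T (p.Gln641*)	not intherited from mother	gene panel	nonsense	discovery
2	F	28	c.5293del p.(Asp1765llefs*13)	de novo	WES	frameshift	discovery
3	M	8	c.2612del p.(Ala871Valfs*4)	de novo	WES	frameshift	discovery
4	F	20	c.2426-1G>A	NA	NA	splice site	discovery
5	F	12	c.2773+1G>A	de novo	gene panel	splice site	discovery
6	F	19	2q36.3(229824569_230111952) × 1 Deletion exons 1–7	de novo	array CGH	deletion	discovery
7	M	9	2q36.3(229796589_229802461) × 1Deletion exons 20–24	not intherited from mother	WES	deletion	discovery
8	F	13	c.5576C>G p.(Pro1859Arg)	de novo	NA	missense	discovery
9	F	9	c.4628del p.(Pro1543Leufs*11)	de novo	WES	frameshift	discovery
10	F	3	c.4068_4069dup p.Met1357Thrfs*2	de novo	trio WES	frameshift	discovery
11	M	10	c.2771A>T p.(Glu924Val)	de novo	trio WES	missense	discovery
12	F	17	c.1192G>T p.(Glu398*)	de novo	gene panel	nonsense	discovery
13	F	21	c.1507C>T p.(Arg503*)	de novo	WES	nonsense	discovery
14	M	10	c.1507C>T p.(Arg503*)	de novo	gene panel	nonsense	discovery
15	F	4	c.2361_2362del p.(Asn787Lysfs*14)	de novo	trio WES	frameshift	discovery
16	F	12	c.3361C>T p.(Gln1121*)	de novo	gene panel	nonsense	discovery
17	M	7	c.3583del p.(Ser1195Leufs*24)	de novo	gene panel	frameshift	discovery
18	F	21	c.3828_3829del p.(Ala1277Lysfs*13)	de novo	NA	frameshift	discovery
19	M	65	c.5411dup p.(Lys1805Glufs*28)	NA	WES	frameshift	discovery
20	F	22	c.5583+1G>A	de novo	gene panel	splice site	discovery
21	F	66	c.2482C>G p.(Pro828Ala)	de novo	WES	missense	discovery_outlier
22	M	2	c.5800 C>A p.Pro1934Thr	de novo	WES	missense	discovery_outlier
23	F	8	c.1503_1511del p.Cys502_Ala504del)	de novo	WGS	in-frame	validation_VUS
24	M	11	c.3743+1G>A	de novo	trio WGS	splice site	validation
25	F	14	c.1025_1026ins44 p. (Ser343Cysfs*17)	NA	NA	frameshift	validation
26	F	7	c.1983delC p.(Ile662Phefs*2)	de novo	WES	frameshift	validation
27	F	8	c.1896_1911+30del p.(Asn632Lysfs*21)	de novo	trio WES	frameshift	validation
28	M	13	2q36.3(229810880_229836984) × 1Deletion exons 5–14	de novo	trio WES, array CGH	deletion	validation
29	M	7	c.3370del p.(Cys1124Valfs*19)	de novo	WES	frameshift	validation
30	M	21	c.1132C>T p.(Gln378*)	de novo	WES	nonsense	validation
31	M	3	c.1132C>T p.(Gln378*)	inherited from affected father	Sanger sequencing	nonsense	validation
32	F	18	c.1195dup p.(Met399Asnfs*31)	de novo	trio WGS	frameshift	validation
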