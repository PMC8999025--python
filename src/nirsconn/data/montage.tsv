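channel	brodmann	x	y	z	weight	roi
1	9	34	45	43	0.85714	dlPFC
2	9	14	55	44	1	dlPFC
3	9	-9	55	45	1	dlPFC
4	9	-28	45	43	0.90498	dlPFC
5	46	43	47	30	0.60444	dlPFC
6	46	25	61	31	0.35887	dlPFC
7	10	4	63	32	0.75357	FPC
8	9	-19	60	33	0.44939	dlPFC
9	46	-40	47	30	0.67544	dlPFC
10	10	35	62	20	0.51373	FPC
11	10	15	70	21	1	FPC
12	10	-10	70	20	1	FPC
13	10	-32	62	19	0.51538	FPC
14	46	45	58	6	0.59144	dlPFC
15	10	25	71	8	0.83502	FPC
16	10	5	72	9	1	FPC
17	10	-21	71	8	0.88372	FPC
18	46	-42	58	6	0.60311	dlPFC
19	11	34	67	-6	0.59649	OFC
20	11	15	73	-4	0.52229	OFC
21	11	-11	73	-3	0.47	OFC
22	11	-32	66	-4	0.51408	OFC
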