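	chromatin	nucleolus	nuclear speckle	PML body	nuclear lamina	nuclear matrix	nuclear envelope	Cajal body	nuclear pore complex	nucleoplasm	kinetochore	spindle apparatus	perinucleolar
chromatin	506	32	11	7	0	6	3	1	1	4	6	1	1
nucleolus	49	461	29	11	4	12	3	6	2	3	2	1	2
nuclear speckle	14	19	153	2	2	4	1	1	0	2	1	0	0
PML body	12	13	9	38	2	3	2	1	1	0	1	0	0
nuclear lamina	5	6	3	2	41	3	7	0	2	0	1	0	0
nuclear matrix	7	9	5	4	2	25	1	0	0	1	0	0	0
nuclear envelope	4	4	1	0	3	1	34	0	6	0	1	0	0
Cajal body	3	5	2	0	1	1	0	10	0	1	0	0	0
nuclear pore complex	4	4	1	2	3	0	6	0	15	0	1	0	0
nucleoplasm	39	38	30	11	7	8	5	10	3	13	2	1	2
kinetochore	4	5	0	1	1	0	1	1	2	2	5	0	0
spindle apparatus	32	27	19	8	10	9	7	5	1	1	1	8	1
perinucleolar	0	3	0	0	0	0	0	1	0	0	0	0	4
None	18	27	29	9	4	2	2	6	1	2	4	3	3
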