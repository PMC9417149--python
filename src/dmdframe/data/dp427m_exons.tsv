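# transcript_id: Dp427m (dystrophin muscle isoform, RefSeq NM_004006)
# convention: coding (CDS) nucleotides per exon, stop codon included in exon 79
# exon 1 length covers CDS only (5'UTR excluded); exon 79 covers CDS only (3'UTR excluded)
# total_coding_nt: 11058
exon_index	coding_length_nt
1	235
2	62
3	97
4	75
5	53
6	123
7	119
8	182
9	69
10	129
11	182
12	151
13	120
14	105
15	108
16	180
17	176
18	123
19	88
20	242
21	181
22	146
23	213
24	114
25	156
26	171
27	183
28	150
29	138
30	162
31	111
32	174
33	156
34	171
35	180
36	129
37	171
38	123
39	138
40	153
41	183
42	195
43	173
44	148
45	176
46	148
47	150
48	186
49	102
50	109
51	233
52	118
53	212
54	155
55	190
56	173
57	145
58	121
59	269
60	147
61	78
62	61
63	62
64	75
65	202
66	89
67	112
68	148
69	102
70	167
71	39
72	66
73	66
74	158
75	244
76	123
77	152
78	32
79	10
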