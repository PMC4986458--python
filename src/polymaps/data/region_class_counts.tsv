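# Published 1-kb-region classification tallies for the four wild octoploid
#	strawberry subgenomes (Av, Bi, B1, B2) across the seven haploid
#	Fragaria chromosomes, from the targeted-capture linkage-map study of
#	F. virginiana and F. chiloensis.  "clusters" is the cluster count
#	behind the clustered introgression-like regions.
signal	subgenome	c1	c2	c3	c4	c5	c6	c7
supportive	Av	54	120	55	97	118	198	90
supportive	Bi	44	117	78	93	91	175	102
supportive	B1	60	104	43	67	84	120	72
supportive	B2	61	104	46	91	86	113	59
clustered_introgression_like	Av	0	0	0	0	0	0	0
clustered_introgression_like	Bi	2	4	4	0	11	2	5
clustered_introgression_like	B1	10	7	16	15	2	19	25
clustered_introgression_like	B2	6	0	0	0	4	3	17
clusters	Av	0	0	0	0	0	0	0
clusters	Bi	1	2	2	0	4	1	1
clusters	B1	2	2	5	3	1	8	5
clusters	B2	3	0	0	0	2	1	5
isolated_introgression_like	Av	2	4	3	6	4	8	7
isolated_introgression_like	Bi	6	4	7	6	11	8	3
isolated_introgression_like	B1	4	7	5	6	3	17	12
isolated_introgression_like	B2	5	5	7	9	5	10	9
outgroup_homoplasy	Av	2	6	3	6	6	10	18
outgroup_homoplasy	Bi	1	2	4	3	3	10	7
outgroup_homoplasy	B1	2	7	5	5	3	14	16
outgroup_homoplasy	B2	8	6	5	2	10	19	13
support_homoplasy	Av	1	5	3	6	5	7	4
support_homoplasy	Bi	1	6	1	3	4	8	8
support_homoplasy	B1	3	9	3	8	6	16	10
support_homoplasy	B2	2	10	6	5	10	11	13
informative_regions	All	160	298	185	230	255	421	264
informative_markers	All	317	645	367	483	568	902	536
total_markers	All	540	1152	627	784	905	1517	956
percent_missing	All	64.5	64.5	64.5	63.2	64.1	63.9	64.6
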