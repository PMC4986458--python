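# Published introgression clusters for the wild octoploid strawberry maps:
#	reference pseudochromosome, first and last member marker site,
#	subgenome of the affected linkage groups, count of adjacent ~1-kb
#	member regions, and the parental maps in which the event is observed.
chromosome	start	end	subgenome	regions	maps
1	5065413	5220128	Bi	2	Fvirg-p
1	427431	447178	B2	2	Fchil-p,Fvirg-p
1	2235284	2394395	B2	2	Fvirg-m,Fvirg-p
1	3893160	4468792	B2	2	Fchil-m,Fvirg-m
1	427431	1390854	B1	8	Fchil-m,Fchil-p,Fvirg-m,Fvirg-p
1	3893160	4468792	B1	2	Fvirg-m,Fvirg-p,Fchil-m
2	22607224	22676892	Bi	2	Fvirg-m,Fvirg-p
2	17223334	17302784	B1	2	Fvirg-m,Fvirg-p
2	25578591	26245090	B1	5	Fchil-m,Fchil-p,Fvirg-m,Fvirg-p
2	5110972	5139963	Bi	2	Fvirg-m,Fvirg-p
3	30308416	30469404	Bi	2	Fchil-m,Fvirg-p
3	32852305	32955512	Bi	2	Fchil-m,Fchil-p
3	124040	759546	B1	2	Fchil-p,Fvirg-p
3	2067176	2179483	B1	4	Fvirg-m,Fvirg-p
3	4625730	4646210	B1	2	Fvirg-m,Fvirg-p
3	6728933	6815506	B1	3	Fvirg-m,Fvirg-p,Fchil-m
3	7342503	8226577	B1	5	Fchil-m,Fchil-p,Fvirg-m,Fvirg-p
4	22867544	23893840	B1	10	Fchil-m,Fchil-p,Fvirg-m,Fvirg-p
4	26100382	26165868	B1	2	Fchil-m,Fvirg-m
4	32133852	32406162	B1	3	Fchil-m,Fvirg-m
5	275987	481317	Bi	4	Fvirg-m,Fvirg-p,Fchil-p
5	23910116	23947199	Bi	3	Fchil-m,Fchil-p,Fvirg-m
5	28429618	28438057	Bi	2	Fvirg-m,Fvirg-p
5	28912695	29086611	Bi	2	Fvirg-m,Fvirg-p
5	10990292	10992194	B2	2	Fvirg-m,Fvirg-p
5	28429618	28438057	B2	2	Fchil-m,Fchil-p,Fvirg-p
5	17792748	17936726	B1	2	Fvirg-m,Fvirg-p
6	25670424	26071024	Bi	2	Fchil-p,Fvirg-p
6	34884370	34958872	B2	3	Fchil-p
6	127855	704274	B1	4	Fchil-m,Fchil-p,Fvirg-p
6	1024942	1107448	B1	3	Fvirg-m,Fvirg-p,Fchil-p
6	7767792	7780026	B1	2	Fvirg-m,Fvirg-p
6	10737836	10761718	B1	2	Fvirg-m,Fvirg-p,Fchil-m
6	11163923	11407930	B1	2	Fvirg-m,Fvirg-p,Fchil-p
6	27838353	27895788	B1	2	Fchil-m,Fvirg-m
6	34652543	34656025	B1	2	Fchil-m,Fchil-p
6	38080971	38105006	B1	2	Fchil-m,Fvirg-m
7	16085862	16472060	Bi	5	Fchil-m,Fchil-p,Fvirg-m
7	2247584	2857258	B2	2	Fvirg-m,Fvirg-p
7	5329113	5933718	B2	3	Fvirg-m,Fvirg-p
7	6727176	7011896	B2	4	Fchil-m,Fchil-p,Fvirg-m,Fvirg-p
7	8420008	8481933	B2	2	Fchil-m,Fvirg-m
7	9296554	10605847	B2	6	Fchil-m,Fchil-p,Fvirg-m,Fvirg-p
7	7246522	7567127	B1	3	Fchil-m,Fchil-p,Fvirg-p
7	14121260	14312154	B1	2	Fvirg-m,Fvirg-p
7	16665708	18245006	B1	11	Fchil-m,Fchil-p,Fvirg-m,Fvirg-p
7	21644908	22959952	B1	6	Fchil-m,Fchil-p,Fvirg-p
7	23427780	23594132	B1	3	Fvirg-m,Fvirg-p,Fchil-p
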