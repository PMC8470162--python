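snp_id	position	gene	stage	count_g1	count_g2	count_g3	count_nocall
rs1999241	chr10:26277498	GAD2	A	34	44	4	1
rs1999241	chr10:26277498	GAD2	B	17	6	11	0
rs7645985	chr3:194777389	LINC01968	A	78	4	1	0
rs7645985	chr3:194777389	LINC01968	B	21	13	0	0
rs6516709	chr21:25893395	APP	A	37	43	3	0
rs6516709	chr21:25893395	APP	B	12	11	11	0
rs6078354	chr20:11820605	LINC00687	A	3	22	58	0
rs6078354	chr20:11820605	LINC00687	B	7	17	10	0
rs7725201	chr5:180102124	RASGEF1C	A	45	38	0	0
rs7725201	chr5:180102124	RASGEF1C	B	19	9	6	0
rs10859918	chr12:95652910	PGAM1P5	A	45	26	11	1
rs10859918	chr12:95652910	PGAM1P5	B	8	23	3	0
rs6110516	chr20:15097697	MACROD2	A	13	70	0	0
rs6110516	chr20:15097697	MACROD2	B	13	18	3	0
rs4693641	chr4:83755117	None	A	83	0	0	0
rs4693641	chr4:83755117	None	B	27	1	6	0
rs5928104	chrX:32899133	DMD	A	3	80	0	0
rs5928104	chrX:32899133	DMD	B	0	27	7	0
rs8084397	chr18:76251014	LOC105372209; LOC105372210	A	58	19	5	1
rs8084397	chr18:76251014	LOC105372209; LOC105372210	B	10	21	3	0
rs4715127	chr6:49320956	None	A	6	22	55	0
rs4715127	chr6:49320956	None	B	0	22	12	0
rs2496369	chr6:49156247	None	A	1	25	57	0
rs2496369	chr6:49156247	None	B	4	19	11	0
Affx-2716217	chr10:126685478	DOCK1	A	53	23	7	0
Affx-2716217	chr10:126685478	DOCK1	B	12	21	1	0
rs56352414	chr22:48917877	None	A	50	32	1	0
rs56352414	chr22:48917877	None	B	16	10	8	0
rs2806810	chr13:103997325	None	A	38	42	3	0
rs2806810	chr13:103997325	None	B	9	16	9	0
rs4934985	chr10:33616333	None	A	5	30	48	0
rs4934985	chr10:33616333	None	B	12	13	8	1
rs6912291	chr6:110065139	None	A	1	34	48	0
rs6912291	chr6:110065139	None	B	6	3	25	0
rs201036	chr6:6708885	LOC101928047; LOC101928004	A	32	39	12	0
rs201036	chr6:6708885	LOC101928047; LOC101928004	B	2	17	15	0
rs9965164	chr18:76220796	LOC105372208	A	59	19	5	0
rs9965164	chr18:76220796	LOC105372208	B	10	21	3	0
rs3813579	chr16:79715379	LOC105371356	A	43	31	9	0
rs3813579	chr16:79715379	LOC105371356	B	5	21	8	0
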