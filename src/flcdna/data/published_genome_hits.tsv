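acc	length_bp	matched_bp	query_start	query_end	chrom	n_blocks	aligned_region
FS722584	827	765	62	827	chr11	6	NAT10 (Intron,Exon)
FS723598	889	648	69	717	chr1	8	Intergenic
FS723503	850	598	252	850	chr2	3	Intergenic
FS723108	829	770	59	829	chr11	7	Intergenic
FS723805	823	627	57	684	chr5	2	PPP2R2B (Intron)
FS722908	835	774	61	835	chr3	6	Intergenic
FS723536	865	776	78	854	chr7	4	Intergenic
FS723202	936	758	155	913	chr5	6	Intergenic
FS722459	525	462	63	525	chr7	2	LOC493754 (Intron)
FS722694	849	795	54	849	chr14	7	Intergenic
FS723758	861	807	54	861	chr3	7	DVL3 (Intron,Exon), AP2M1 (Intron)
FS723877	964	900	60	960	chr7	5	MKLN1 (Intron)
FS723612	933	876	56	932	chr15	3	Intergenic
FS722689	942	720	222	942	chr1	8	FLEKHA6 (Intron)
FS723970	222	188	34	222	chr11	2	TIMM10 (Intron,Exon)
FS723532	1000	645	57	702	chr16	7	GABARAPL2 (Exon, Intergenic)
FS723424	943	546	59	605	chr20	2	ITCH (Intron, Exon)
FS723884	955	678	57	735	chr17	7	SCN4A (Intron)
FS723781	961	900	61	961	chrX	10	Intergenic
FS723422	972	752	61	813	chr15	10	Intergenic
FS724052	843	752	88	840	chr3	6	ITPR1 (Intron)
FS722839	934	868	48	916	chr5	3	IL4 (Intron)
FS723579	853	735	118	853	chr9	7	Intergenic
FS722478	938	768	57	825	chr22	5	Intergenic
FS723804	867	800	62	862	chr6	2	PKHD1 (Intron)
FS723444	967	795	172	967	chr7	5	Intergenic
FS723329	921	859	62	921	chr11	12	Intergenic
FS723221	954	560	153	713	chr1	3	Intergenic
FS723414	1013	946	48	994	chr2	7	Intergenic
FS723140	816	701	115	816	chr2	5	Intergenic
FS722423	886	822	64	886	chr2	4	MYEOV2 (Intron)
FS722597	913	648	118	766	chr4	6	Intergenic
FS723463	939	632	61	693	chr21	5	Intergenic
FS723411	241	184	56	240	chr7	3	Intergenic
FS723556	891	833	57	890	chr16	7	Intergenic
FS723572	771	706	65	771	chr6	4	Intergenic
FS722560	943	880	61	941	chr10	6	NPR1 (Intron)
FS723477	1024	557	106	663	chr2	5	Intergenic
FS723929	957	727	230	957	chr10	5	Intergenic
FS723671	174	93	62	155	chr17	2	ORMDL3 (Intron)
FS724061	855	477	29	506	chr2	6	Intergenic
FS722691	864	637	39	676	chr6	4	Intergenic
FS723333	941	847	62	909	chrX	5	Intergenic
FS722546	1021	933	63	996	chr6	11	GMPR (Intron)
FS723142	886	762	76	838	chr20	4	SLC13A3 (Intron)
FS723357	756	691	65	756	chr6	6	BET3L (Intron)
FS722638	961	894	41	935	chr9	6	Intergenic
FS723442	887	654	41	695	chr1	4	Intergenic
FS723880	810	695	46	741	chr21	9	HUNK (Intron,Intergenic)
FS723438	1012	556	422	978	chr9	8	Intergenic
FS723883	624	393	181	574	chr10	3	Intergenic
FS723617	1034	966	48	1014	chr9	12	VLDLR (Intron)
FS723491	859	575	55	630	chr17	2	Intergenic
FS723767	885	636	63	699	chr9	2	AUH (Exon, Intron)
FS723901	822	591	137	728	chr2	6	C2orf67 (Intron)
FS723913	891	791	60	851	chr1	8	Intergenic
FS723200	832	750	66	816	chr5	6	Intergenic
FS723126	854	799	55	854	chr9	5	Intergenic
FS723264	1039	976	56	1032	chr1	5	PLXNA2 (Intron)
FS724105	746	379	136	515	chr3	3	Intergenic
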