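variant_id	gene	location	nucleotide_change	protein_change	consequence	subcategory	af_exome_fin	af_genome_fin	af_exome_global	af_genome_global	sift	polyphen	revel	cadd_phred
rs193219754	MLH3	chr14:75039918	c.3563C>G	p.Ser1188Ter	stop gained		0.002491	0.003159	NA	NA	NA	NA	NA	42
rs180177100	PALB2	chr16:23635306	c.1240C>T	p.Arg414Ter	stop gained		0	0	NA	NA	NA	NA	NA	37
rs11574410	WRN	chr8:31173019	c.4216C>T	p.Arg1406Ter	stop gained		0.0006469	0.0002832	NA	NA	NA	NA	NA	36
rs81002862	BRCA2	chr13:32380005	c.9118-2A>G	NA	splice acceptor		0.0003697	0.0001885	NA	NA	NA	NA	NA	35
rs11571833	BRCA2	chr13:32398489	c.9976A>T	p.Lys3326Ter	stop gained		0.01086	0.01045	NA	NA	NA	NA	NA	35
rs5745908	NEIL1	chr15:75349341	c.434+2T>C	NA	splice donor		0.0018	0.001508	NA	NA	NA	NA	NA	34
rs587782401	CHEK2	chr22:28734401	c.319+2T>A	NA	splice donor		0.0005548	0.0003764	NA	NA	NA	NA	NA	34
rs766240074	RAD54L	chr1:46273748	c.1610+1G>A	NA	splice donor		4.968e-05	0	NA	NA	NA	NA	NA	33
chr4:2490336 G/T	RNF4	chr4:2490336	c.-157-1G>T	NA	splice acceptor		NA	NA	NA	NA	NA	NA	NA	33
rs756188698	RAD18	chr3:8899048	c.1169-1G>C	NA	splice acceptor		0.0002398	9.457e-05	NA	NA	NA	NA	NA	28.9
rs11572913	GTF2H3	chr12:123633862	c.3G>A	p.Met1?	start lost		0.0007112	0.000565	NA	NA	0.02	0.273	NA	24.8
rs187418762	SPIDR	chr8:47713484	c.2189-5G>A	NA	splice region, splice polypyrimidine tract, intron		0.01286	0.01198	NA	NA	NA	NA	NA	20.5
rs149243307	FANCI	chr15:89260841	c.286G>A	p.Glu96Lys	missense, splice region	2	0.001848	0.001507	NA	NA	0	1	0.448	33
rs41540016	POLQ	chr3:121436275	c.7390G>A	p.Ala2464Thr	missense, splice region	2	0.01381	0.01208	NA	NA	0	1	0.84	33
chr1:241861448 -/T	EXO1	chr1:241861447-241861448	c.987dup	p.Lys330Ter	frameshift	1	NA	NA	NA	NA	NA	NA	NA	33
rs773570504	ATM	chr11:108326152-108326153	c.6908dup	p.Glu2304GlyfsTer69	frameshift	1	4.625e-05	9.56e-05	NA	NA	NA	NA	NA	33
rs762390984	FANCI	chr15:89301393-89301405	c.2957_2969del	p.Val986AlafsTer39	frameshift	1	0.002957	0.002454	NA	NA	NA	NA	NA	33
rs759217526	FANCL	chr2:58159793-58159794	c.1096_1099dup	p.Thr367AsnfsTer13	frameshift	1	0.001814	0.002649	NA	NA	NA	NA	NA	33
rs199791286	MSH3	chr5:80778737	c.2336G>A	p.Arg779His	missense	1	0.001294	0.001415	NA	NA	0	1	0.884	32
chr8:31111721 G/C	WRN	chr8:31111721	c.2195G>C	p.Arg732Pro	missense	2	NA	NA	NA	NA	0	1	0.499	31
chr12:132677395 -/T	POLE	chr12:132677394-132677395	c.769dup	p.Ile257AsnfsTer6	frameshift	1	NA	NA	NA	NA	NA	NA	NA	31
rs28363284	RAD51D	chr17:35103294	c.698A>G	p.Glu233Gly	missense	1	0.001185	0.001797	NA	NA	0.04	0.973	NA	29.9
rs746243211	MSH3	chr5:80672754	c.923A>T	p.Lys308Met	missense	1	0	0	NA	NA	0	1	0.823	29.7
rs137923123	PER1	chr17:8147713	c.1349G>A	p.Arg450His	missense	1	0.003681	0.002823	NA	NA	0	1	NA	29.2
rs373080718	TOP3A	chr17:18277728	c.2774C>T	p.Pro925Leu	missense	1	4.623e-05	0	NA	NA	0.01	0.999	NA	29
rs2306211	POLQ	chr3:121432937	c.7640C>T	p.Ala2547Val	missense	2	0.007347	0.006223	NA	NA	0.03	1	0.571	28.8
rs200535477	RECQL5	chr17:75627670	c.2828G>A	p.Arg943His	missense	1	0.009798	0.008201	NA	NA	0	1	NA	28.7
rs202068855	RPA1	chr17:1880615	c.1165C>T	p.Arg389Trp	missense	2	0.01502	0.0152	NA	NA	0	1	NA	28.1
rs144564120	ERCC2	chr19:45352249	c.2150C>G	p.Ala717Gly	missense	1	4.624e-05	0	NA	NA	0.01	0.015	NA	28.1
rs28897758	BRCA2	chr13:32394734	c.1267T>G	p.Cys423Gly	missense	1	0.0004619	0.000659	NA	NA	0	1	0.788	28
rs34001746	TOP3A	chr17:18285268	c.1751T>G	p.Leu584Arg	missense	1	0.0004619	0.000659	NA	NA	0.02	0.803	NA	27.3
rs121913016	ERCC2	chr19:45357368	c.1381C>G	p.Leu461Val	missense	1	4.633e-05	0	NA	NA	0	0.982	NA	27.3
rs1805378	NTHL1	chr16:2044652	c.503T>C	p.Ile168Thr	missense	1	0.0004352	0.0003766	NA	NA	0	1	0.876	27.1
rs34642881	RECQL4	chr8:144517415	c.212A>G	p.Glu71Gly	missense, splice region	1	0.004511	0.005941	NA	NA	0.02	0.803	NA	26.6
rs17879961	CHEK2	chr22:28725099	c.470T>C	p.Ile157Thr	missense	1	0.004511	0.005941	NA	NA	0.07	0.514	NA	26.5
rs142213781	NEIL1	chr15:75353853	c.833C>T	p.Thr278Ile	missense	2	0.002086	0.002352	NA	NA	0	1	0.563	26.4
rs562132292	ERCC2	chr19:45357290	c.1459C>T	p.Arg487Trp	missense	1	0.0003272	0.0006591	NA	NA	0	0.998	NA	26.4
chr6:37360499 C/G	RNF8	chr6:37360499	c.165C>G	p.Cys55Trp	missense	2	NA	NA	NA	NA	0	1	0.747	26.3
rs149253459	FAAP100	chr17:81547649	c.1433A>G	p.Gln478Arg	missense	1	0.002894	0.0016	NA	NA	0.01	0.997	NA	26.2
rs750771205	ATM	chr11:108289000	c.4133C>T	p.Pro1378Leu	missense	2	0	0	NA	NA	0	0.969	0.546	26.1
rs1801673	ATM	chr11:108304736	c.5558A>T	p.Asp1853Val	missense	2	0.003699	0.00292	NA	NA	0	0.987	0.589	26.1
rs1799802	ERCC4	chr16:13934224	c.1135C>T	p.Pro379Ser	missense	2	0.007207	0.009714	NA	NA	0	1	0.526	25.4
rs11212587	ATM	chr11:108315883	c.6067G>A	p.Gly2023Arg	missense	2	0.0008318	0.0007553	NA	NA	0	0.364	0.511	25.3
rs61752784	POLG	chr15:89330133	c.803G>C	p.Gly268Ala	missense	1	0.004158	0.00546	NA	NA	0	0.999	0.967	25.3
rs200981995	LIG3	chr17:34999827	c.2302T>C	p.Tyr768His	missense	2	0.01173	0.009134	NA	NA	0.11	0.994	NA	25.1
chr17:18292743 T/A	TOP3A	chr17:18292743	c.1183A>T	p.Ser395Cys	missense	1	NA	NA	NA	NA	0.01	0.976	NA	25
rs201920810	SPIDR	chr8:47712713	c.2029G>A	p.Asp677Asn	missense	2	0	0	NA	NA	0	1	0.561	24.9
rs140566004	POLE	chr12:132673646	c.1288G>A	p.Ala430Thr	missense	2	0.0001395	0	NA	NA	0	0.997	0.487	24.7
rs78488552	WRN	chr8:31154721	c.3785C>G	p.Thr1262Arg	missense	2	0.000231	9.432e-05	NA	NA	0	0.999	0.413	24.5
rs546221341	POLQ	chr3:121488663-121488669	c.4262_4268del	p.Ile1421ArgfsTer8	frameshift	1	0.006209	0.005384	NA	NA	NA	NA	NA	24.3
rs145289229	POLG	chr15:89328532	c.1174C>G	p.Leu392Val	missense	1	0.007823	0.01085	NA	NA	0.06	0.999	0.796	24.2
rs55748151	POLQ	chr3:121533021	c.929T>G	p.Val310Gly	missense	2	0.001063	0.001413	NA	NA	0	0.552	0.498	24.1
rs150018949	EXO5	chr1:40515573-40515574	c.1029_1030insG	p.Arg344AlafsTer10	frameshift	1	0.004352	0.003488	NA	NA	NA	NA	NA	24.1
rs771308001	ERCC1	chr19:45407145-45407146	NA	NA	downstream gene	1	0.003376	0.00311	NA	NA	NA	NA	NA	23.7
rs565251228	RECQL5	chr17:75624891	NA	NA	downstream gene	1	0.0001461	0.0002827	NA	NA	NA	NA	NA	23.4
rs55801750	ATM	chr11:108330296	c.7390T>C	p.Cys2464Arg	missense	2	4.619e-05	0	NA	NA	0.1	0.005	0.668	22.9
rs201503405	PNKP	chr19:49862573	c.901C>T	p.Arg301Trp	missense	1	0.006464	0.006775	NA	NA	0	0.911	NA	22.9
chr19:45352306 T/C	ERCC2	chr19:45352306	c.2093A>G	p.Gln698Arg	missense	1	NA	NA	NA	NA	0.54	0.218	NA	22.8
chrX:153444976 C/G	TREX2	chrX:153444976	c.455G>C	p.Arg152Pro	missense	1	NA	NA	NA	NA	0	0.999	NA	22.7
rs775001669	MLH3	chr14:75048767	c.889C>T	p.Arg297Trp	missense	2	0.00134	0.001132	NA	NA	0	1	0.655	22.6
rs41549716	POLG	chr15:89321842	c.2492A>G	p.Tyr831Cys	missense	2	0.01803	0.0161	NA	NA	0.02	0.995	0.732	22.6
rs201414369	EME1	chr17:50380824	c.1598G>A	p.Arg533His	missense	1	0.0001386	0.0001884	NA	NA	0.22	0.994	NA	22.6
rs144340710	TP53	chr17:7674259	c.704A>G	p.Asn235Ser	missense	1	0.0002772	0.0004745	NA	NA	0.22	0.385	NA	22.5
rs4987202	RAD23A	chr19:12948812	c.599C>T	p.Thr200Met	missense, splice region	1	0.004359	0.003299	NA	NA	0.43	0.02	NA	22.5
rs146309259	LIG1	chr19:48121298	c.2257G>A	p.Val753Met	missense	1	0.002451	0.001788	NA	NA	0.06	0.407	NA	22.5
rs28897689	BRCA1	chr17:43091492	c.4039A>G	p.Arg1347Gly	missense	1	0.001944	0.001788	NA	NA	0.09	0.255	NA	22.2
rs55712212	BRCA2	chr13:32341176	c.6821G>T	p.Gly2274Val	missense	2	0.01303	0.01349	NA	NA	0.37	0.966	0.481	21.8
rs144276604	XAB2	chr19:7625912	c.790G>A	p.Asp264Asn	missense	1	0.0002318	0	NA	NA	0.09	0.846	NA	21.7
rs3730947	LIG1	chr19:48140013	c.1045G>A	p.Val349Met	missense	2	0.01564	0.01648	NA	NA	0	0.997	NA	21.5
rs776329282	ERCC4	chr16:13926750-13926755	c.580_584+1del	NA	in-frame deletion, splice region	1	9.256e-05	0.0001884	NA	NA	NA	NA	NA	20.5
rs763165669	NTHL1	chr16:2038404-2038416	NA	NA	downstream gene	2	0.01363	0.007775	NA	NA	NA	NA	NA	NA
rs41547220	POLQ	chr3:121489857-121489859	c.3072_3074del	p.Lys1025del	in-frame deletion	2	0.01831	0.01925	NA	NA	NA	NA	NA	NA
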