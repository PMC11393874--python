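patient_id	lund_negative	age1	age2	triple_negative	histology	variant_ids
424	0	25	NA	0	Ductal, G3, ER+, PR-, Her2+	rs145289229,rs11571833,rs2306211,rs546221341
425	0	27	NA	0	Ductal, G3, ER+, PR+, Her2-
426	0	27	NA	NA	Ductal, G3, ER-, PR-, Her2 NA
427	0	28	NA	0	Ductal, G3, ER+, PR+, Her2+
428	0	28	NA	1	Ductal, G3, ER-, PR-, Her2-	rs11571833,rs3730947
429	0	28	NA	0	Ductal, G3, ER+, PR+, Her2+
431	0	28	NA	0	Ductal, G3, ER-, PR+, Her2+	rs140566004,rs4987202
432	1	30	NA	0	Ductal, G3, ER+, PR+, Her2-	rs201920810,rs773570504
433	0	31	35	1	Ductal, G3, ER-, PR-, Her2-; 2 Ductal, ER+, Her2-; known homozygous FANCM c.5101C>T
434	1	31	NA	1	Ductal, G3, ER-, PR-, Her2-	rs200535477,rs2306211
435	1	32	NA	0	Ductal, G3, ER-, PR-, Her2+	chr6:37360499 C/G,rs78488552,rs565251228
436	1	32	NA	0	Micropapillar, ER+, PR+, Her2-	rs1801673,rs762390984,rs763165669
437	0	33	NA	NA	DCIS, G3	rs373080718,rs202068855
438	1	33	NA	1	Ductal, G3, ER-, PR-, Her2-	rs187418762
440	0	34	37	NA	Ductal, G3, ER-, PR-; 2 LCIS	rs55712212,rs137923123,chr19:45352306 T/C
441	1	34	NA	0	Ductal, G3, ER+, PR+, Her2-
442	0	34	NA	0	Ductal, G3, ER+, PR+, Her2-	rs41547220,rs149253459
443	1	34	NA	1	Ductal, G3, ER-, PR-, Her2-	rs766240074,rs562132292
444	1	35	NA	0	Ductal, G3, ER-, PR-, Her2+
445	0	35	43	0	Ductal, G3, ER-, PR-, Her2+; 2 Ductal, G3, ER-, PR-, Her2+	rs587782401
446	1	34	NA	0	Ductal, G2, ER+, PR+, Her2-	rs771308001
610	0	40	40	0	Ductal, G1, ER+, PR+, Her2-; 2 G3, ER+, PR+, Her2-	rs28897758,rs1805378
611	0	40	54	0	Ductal, G2, ER+, PR-, Her2-; 2 ductal, G2, ER+, PR+, Her2-
612	0	40	NA	NA	DCIS	rs81002862,rs11212587
613	0	35	NA	NA
614	0	26	NA	NA	DCIS, G3
615	0	30	NA	1	Ductal, G3, ER-, PR-, Her2-	rs55748151
616	0	38	NA	0	Ductal, G3, ER-, PR-, Her2+	rs55801750,rs34001746,rs144276604
617	0	40	67	0	2 Ductal G3, ER+, PR+, Her2-	rs746243211,chrX:153444976 C/G
618	0	27	NA	0	Ductal, G2, ER+, PR+, Her2-	rs776329282
619	0	27	NA	1	Ductal, G3, ER-, PR-, Her2-	rs5745908,rs41549716,chr17:18292743 T/A,rs41540016
61	0	36	NA	0	Ductal, ER+, PR+, Her2-	rs121913016,rs180177100,rs144564120
620	0	35	NA	0	Ductal, G2, ER+, PR+, Her2-
621	0	39	NA	NA	Lobular	rs55712212
622	0	38	NA	0	Ductal, G2, ER+, PR+, Her2+
623	0	31	NA	0	Ductal, G2, ER+, PR+, Her2+	chr4:2490336 G/T
624	0	23	NA	0	Ductal, G3, ER+, PR+, Her2+	rs149243307,rs61752784,rs17879961,chr1:241861448 -/T
625	0	28	NA	0	Lobular, G2, ER+, PR+, Her2-	rs3730947
626	0	34	34	0	Ductal, ER+, PR+, Her2+; 2 DCIS	rs750771205,rs145289229,rs146309259,rs3730947,rs587782401
627	0	33	NA	NA
628	0	28	NA	1	Ductal, G3, ER-, PR-, Her2-	rs28363284,rs41540016
629	1	40	NA	NA		rs150018949
62	0	36	NA	NA	DCIS
630	0	26	NA	1	Ductal, G3, ER-, PR-, Her2-	rs1799802
631	1	31	NA	0	Ductal, G2, ER+, PR-, Her2-	rs193219754
632	0	38	67	0	Ductal; 2 ductal, G3, ER+, PR+, Her2-	rs187418762,rs4987202,rs201503405
633	1	32	NA	0	Lobular, G2, ER+, PR+, Her2-	rs41540016
634	1	34	NA	1	Ductal, G3, ER-, PR-, Her2-	chr12:132677395 -/T,rs28897689,chr8:31111721 G/C,rs11574410
635	1	30	NA	0	Ductal, G3, ER+, PR-, Her2-	rs144340710,rs3730947
636	0	24	NA	NA		rs4987202
637	0	31	NA	0	Ductal, G3, ER+, PR+, Her2+	rs150018949
639	1	24	NA	0	Ductal, G3, ER+, PR+, Her2-	rs759217526
63	0	37	46	NA	Ductal, G2; 2 Ductal, G2, ER+, PR+, Her2-	rs11572913
64	0	37	57	0	Ductal, G3, ER+, PR+, Her2-; 2
65	0	38	NA	NA		rs34642881
66	0	39	NA	0	Ductal, G3, ER+, PR+, Her2-	rs202068855,rs756188698
67	0	39	NA	0	Ductal, G1, ER+, PR+, Her2-	rs142213781
68	0	39	47	0	Lobular, G2, ER+, PR+, Her2-; 2 DCIS, G3
69	0	40	NA	1	Ductal, G3, ER-, PR-, Her2-	rs200981995,rs17879961,rs201503405
71	0	29	NA	1	Ductal, G3, ER-, PR-, Her2-
72	1	39	NA	0	Ductal, G3, ER+, PR+, Her2+	rs775001669,rs41540016,rs199791286
73	1	33	NA	NA	DCIS, G3
74	1	36	36	1	Ductal, G3, ER-, PR-, Her2-; 2 ductal, G3, ER-, PR-, Her2-	rs201414369,rs150018949
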