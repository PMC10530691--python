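# GRCh38 chromosome annotation: lengths are assembly-exact; centromere
# intervals are cytoband-level approximations; masked regions are the
# 10 kb telomeric assembly gaps. 1-based closed coordinates.
# 4-column rows: chrom length cen_start cen_end; 3-column rows: chrom mask_start mask_end
chrom	length	cen_start	cen_end
1	248956422	121700000	125100000
2	242193529	91800000	96000000
3	198295559	87800000	94000000
4	190214555	48200000	51800000
5	181538259	46100000	50100000
6	170805979	58500000	62600000
7	159345973	58100000	62100000
8	145138636	43200000	47200000
9	138394717	42200000	45500000
10	133797422	38000000	41600000
11	135086622	51000000	55800000
12	133275309	34700000	37200000
13	114364328	16000000	18900000
14	107043718	16100000	18200000
15	101991189	17500000	20500000
16	90338345	36300000	38400000
17	83257441	22700000	27400000
18	80373285	15400000	21500000
19	58617616	24200000	28100000
20	64444167	25700000	30400000
21	46709983	10900000	13000000
22	50818468	13700000	17400000
X	156040895	58100000	63800000
Y	57227415	10300000	10600000
1	1	10000
1	248946423	248956422
2	1	10000
2	242183530	242193529
3	1	10000
3	198285560	198295559
4	1	10000
4	190204556	190214555
5	1	10000
5	181528260	181538259
6	1	10000
6	170795980	170805979
7	1	10000
7	159335974	159345973
8	1	10000
8	145128637	145138636
9	1	10000
9	138384718	138394717
10	1	10000
10	133787423	133797422
11	1	10000
11	135076623	135086622
12	1	10000
12	133265310	133275309
13	1	10000
13	114354329	114364328
14	1	10000
14	107033719	107043718
15	1	10000
15	101981190	101991189
16	1	10000
16	90328346	90338345
17	1	10000
17	83247442	83257441
18	1	10000
18	80363286	80373285
19	1	10000
19	58607617	58617616
20	1	10000
20	64434168	64444167
21	1	10000
21	46699984	46709983
22	1	10000
22	50808469	50818468
X	1	10000
X	156030896	156040895
Y	1	10000
Y	57217416	57227415
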