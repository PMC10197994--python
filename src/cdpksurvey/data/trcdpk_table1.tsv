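name	locus	chromosome	start	end	group	intron	length_aa
TrCDPK01	chr1.jg4121	Tr1O	29342857	29350032	I	9	652
TrCDPK02	chr11.jg3046	Tr3P	19475967	19479305	I	6	490
TrCDPK03	chr11.jg7419	Tr3P	49699451	49702794	I	6	490
TrCDPK04	chr12.jg3340	Tr4P	22292097	22296685	I	6	525
TrCDPK05	chr13.jg1707	Tr5P	11919089	11925479	I	6	484
TrCDPK06	chr15.jg4289	Tr7P	28188470	28195896	I	6	583
TrCDPK07	chr16.jg1647	Tr8P	11857550	11861634	I	6	501
TrCDPK08	chr4.jg11768	Tr4O	82749599	82756663	I	8	543
TrCDPK09	chr6.jg2442	Tr6O	16667798	16670593	I	6	496
TrCDPK10	chr6.jg2448	Tr6O	16751970	16754761	I	6	496
TrCDPK11	chr7.jg7026	Tr7O	43824351	43827109	I	6	567
TrCDPK12	chr8.jg330	Tr8O	2723857	2728472	I	6	524
TrCDPK13	chr8.jg5721	Tr8O	40260485	40264967	I	6	577
TrCDPK14	chr9.jg3491	Tr1P	23497749	23502201	I	6	577
TrCDPK15	chr9.jg4545	Tr1P	30742384	30748425	I	6	606
TrCDPK16	chr9.jg4549	Tr1P	30758875	30767018	I	7	604
TrCDPK17	chr9.jg4589	Tr1P	31051402	31054840	I	7	606
TrCDPK18	chr10.jg1626	Tr2P	11278235	11282359	II	7	536
TrCDPK19	chr11.jg7540	Tr3P	50482871	50486987	II	7	538
TrCDPK20	chr12.jg6833	Tr4P	44711922	44716107	II	7	511
TrCDPK21	chr13.jg2122	Tr5P	14691325	14695563	II	7	515
TrCDPK22	chr13.jg282	Tr5P	1691449	1695649	II	7	454
TrCDPK23	chr13.jg6349	Tr5P	41734498	41736909	II	7	519
TrCDPK24	chr16.jg6213	Tr8P	44320503	44324769	II	7	413
TrCDPK25	chr16.jg6322	Tr8P	44999858	45004251	II	7	557
TrCDPK26	chr3.jg10857	Tr3O	71946757	71950273	II	7	525
TrCDPK27	chr4.jg4021	Tr4O	29365007	29368523	II	7	525
TrCDPK28	chr4.jg4266	Tr4O	31247499	31249871	II	7	519
TrCDPK29	chr5.jg6878	Tr5O	46579663	46583375	II	7	529
TrCDPK30	chr5.jg6984	Tr5O	47190935	47194811	II	7	529
TrCDPK31	chr5.jg6985	Tr5O	47195769	47197955	II	4	410
TrCDPK32	chr7.jg2061	Tr7O	12628766	12633112	II	7	574
TrCDPK33	chr1.jg1928	Tr1O	14027305	14040793	III	22	1013
TrCDPK34	chr1.jg3552	Tr1O	25810144	25817921	III	8	555
TrCDPK35	chr1.jg3553	Tr1O	25820401	25824560	III	7	528
TrCDPK36	chr11.jg8874	Tr3P	59581528	59592044	III	8	510
TrCDPK37	chr11.jg8876	Tr3P	59596963	59603478	III	10	576
TrCDPK38	chr11.jg8877	Tr3P	59611160	59615352	III	8	519
TrCDPK39	chr12.jg4640	Tr4P	30428711	30431256	III	7	532
TrCDPK40	chr15.jg2533	Tr7P	16933744	16938277	III	7	254
TrCDPK41	chr16.jg464	Tr8P	3255395	3259046	III	6	479
TrCDPK42	chr8.jg5032	Tr8O	35936316	35940504	III	7	490
TrCDPK43	chr9.jg2547	Tr1P	17241045	17244635	III	7	535
TrCDPK44	chr9.jg2588	Tr1P	17548790	17554644	III	6	531
TrCDPK45	chr9.jg6904	Tr1P	46606550	46612048	III	6	531
TrCDPK46	chr11.jg6545	Tr3P	43486048	43493182	IV	10	590
TrCDPK47	chr2.jg5591	Tr2O	37510045	37516429	IV	10	589
TrCDPK48	chr5.jg1099	Tr5O	7718463	7722608	IV	11	554
TrCDPK49	chr5.jg5438	Tr5O	36322713	36329697	IV	10	588
TrCDPK50	chr5.jg999	Tr5O	6993561	7004058	IV	24	1053
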