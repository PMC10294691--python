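coordinate	chipchip	hns	chip_score	genes	site	expr_wt	expr_mut
14763			1	(dnaJ)	NA	(8326)	(4689)
22367			2	ileS	TGTAATCAAACCGAAATA	21580	24295
201079			1	(lpxD)	GGTCACATTACGTTCATG	(9261)	(11591)
260277	x	x	14	phoE/proB	TGTAATAAAAGCGTAAAC	68155/6306	69*/4330
262258			1	(proA)	TGTAATACGGTTGAAACG	(9578)	(6248)
332492	x	x	3	(yahA)	TGTAACAGAAATATCACA	(2246)	(1084*)
401676	x	x	20	phoA	TGTCATAAAGTTGTCACG	310112	1548*
417093	x		11	sbcD/phoB	TTTCATAAATCTGTCATA	274/32731	271/34*
417245	x		5	(phoB)	ATTCACAGCACTGTCATA	(32731)	(34*)
569907		x	6	(ybcK)	TGTCACATCGATGTAATC	(33)	(24)
595521	x		3	cusR/cusC	TGTCATTTTTCTGTCACC	391/208	239/50*
922786			2	cspD/clpS	TGTCACATTCCTGTCAAT	2330/18217	1603/23285
983795			2	(gloC)	TGTCAGGCCGCTGTCATC	(4405)	(7533*)
1015596			7	rmf	ATTCACGCCACTGTCATA	3816	5371
1065537		x	2	agp	AGTCATATTTCTGTCACA	976	1983*
1084845			11	phoH	TGTCATCACTCTGTCATC	37076	13375*
1096396		x	1	(ycdU)	TGTCACAAAAGAATCACT	(53)	(64)
1117391			1	(yceA)	GATAAAAAAATCGTCATG	(560)	(456)
1371360	x	x	5	(ycjM)	GGTCACATTTATTTCATA	(11)	(14)
1447326	x		2	feaR/feaB	TTTCACAGAGCGAAAACG	111/786	379*/1231
1527862		x	1	rhsE	TATCAGAAAAATGTCATG	ND	ND
1577158	x	x	4	(yddB)	CGGCACAAAACTGTCATA	(94)	(99)
1581949	x	x	2	(ydeN)	TGTCAAAAATCAGTAATG	(120)	(119)
1861798			5	(yeaC)	NA	(1355)	(1480)
1874218			1	yoaI/yeaL	TGTCATCAAACTGCCATT	12266/36	28*/67
1948542			1	(nudB)	CGTCACGCCGCTGCAACA	(3654)	(3763)
1978157	x		1	(flhD)	TGACATCAACTTGTCATA	(71)	(57)
2055017			1	amn	TTTCACATTTCTGTGACA	42299	12429*
2137862	x	x	5	wza/yegH	TGTCACAATTCGATCATG	10/2257	15/2498
2240543	x		6	mglB	TGTAACCCGTATGTAACA	1076	772
2438961			8	(yfcJ)	TGTCACGATACTGTCATT	(163)	(187)
2484480		x	2	(evgS)	AGTAACAACCGTGTCACA	(1514)	(3343*)
2743442	x		3	(yfiN)/yfiB	TGACACAAATCTTTAATC	(575)/1293	(656)/1629
2799166			1	(alaE)	AGTCACGCTTGCGTCATG	(83)	(58)
2819248			1	csrA	TGTAATGTGTTTGTCATT	6539	7460
2976292			4	omrA	GGTCATCAATCTGTAACA	1	3
3031605	x		3	(uacT)	CGTCACATTATTGCAATG	(5)	(4)
3081080	x		2	(tktA)	AGAAATACCGTTGTCATC	(26875)	(27000)
3198259			1	(glnE)	TGTCATCTTCCTGCAACG	(11291)	(9028)
3243474	x		3	(uxaC)/uxaA	TGTCATACACCCGTCACG	(608)/243	(465)/228
3309385			1	(pnp)	CTTCACAGTACCGTCATC	(33309)	(53983*)
3362763	x	x	4	(yhcA)/yhcD	GGTAATAAATATGTCACT	(38)/425	(54)/415
3458489			1	(gspE)	NA	(69)	(51)
3573580			5	glgB	GGTCAAAAAAATGTCACA	21445	17405
3592453	x		35	ugpB	TGTCATCTTTCTGACACC	54461	2830*
3600942			2	rpoH	TTTCATCTCTATGTCACA	7346	4943
3648534			2	(arsR)	GGTAACAGAAATGACATA	(61)	(66)
3672318	x	x	2	yhjB/yhjC	TTTCACAATGTTGTCATG	252/397	218/408
3682037			1	yhjJ	GAACATGAAAATGTCACG	1871	2721
3709177			1	(eptB)	GGTCACCGAGTTGTCATA	(585)	(1126*)
3728905			1	(xylB)	AGTAATCTTTCGGTAATA	(1160)	(836)
3731396		x	1	(xylF)	NA	(46)	(31)
3767949		x	2	(rhsJ)	TTACATACAAATGTAATA	(ND)	(ND)
3776578			6	yibT/yibL	TGTAATAGTTCTGTAACG	5264/1129	2601*/2135*
3911600	x		38	pstS	TGTCATAAAACTGTCATA	239097	310*
3937206	x		3	rbsK	TGTCACCATCAGGTCATA	1452	1701
3990899			1	hemC/cyaA	TTTCACGCCGTTGTAATA	3823/16054	5169/18141
4113746		x	1	(fpr)	CGTAAATGTTTCGTCATC	(4069)	(4643)
4128495			2	metJ/metB	NA	543/1432	524/1263
4142314	x		1	frwA/frwC	TGTAATGTAACCGTCAAT	72/35	60/36
4227508	x		1	(metH)	ATTCACAAATCTGTCACT	(18026)	(25993)
4245063			1	(malF)	TGTCATTAAAAAGAAACA	(486)	(853*)
4325211			2	phnC	ATTAACCAAATCGTCACA	32470	13*
4459250			1	(pmbA)	GGTAACGATATTGAAACA	(11462)	(11004)
4522523		x	1	(yjhG)	NA	(478)	(444)
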