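rank	p	probe_id	gene
8	1.28E-20	10922816	Il1r2
141	2.38E-16	10718351	Fpr1
151	4.18E-16	10922882	Il18rap
198	2.89E-15	10765195	Selp
245	8.84E-15	10754983	Il13ra1
257	1.12E-14	10759604	Mcemp1
258	1.13E-14	10820282	Vcan
283	2.92E-14	10824695	S100a9
288	3.17E-14	10842239	Mmp9
298	4.35E-14	10750460	Ets2
334	1.4E-13	10823970	Tlr2
381	3.4E-13	10737047	Car4
406	5.93E-13	10715258	Entpd1
445	1.24E-12	10890441	Pygl
538	7.39E-12	10825153	Fcgr1a
641	4.43E-11	10777242	Bst1
652	4.7E-11	10803991	Cd14
667	5.67E-11	10751931	Bcl6
746	1.35E-10	10747024	Ccr7
850	4.08E-10	10894549	Ckap4
998	1.28E-09	10834109	Il1rn
1140	4.12E-09	10783203	Rnase2
1337	2.07E-08	10732652	Dusp1
1385	2.79E-08	10723156	Iqgap1
1414	3.19E-08	10865369	C3ar1
1533	5.96E-08	10703443	Fpr2
1767	2.18E-07	10894878	Lta4h
1799	2.67E-07	10761025	Pilra
1925	4.86E-07	10869476	Orm1
2033	7.88E-07	10791677	Acsl1
2124	1.23E-06	10850530	Cd93
2264	1.96E-06	10866459	Plbd1
2358	2.59E-06	10854733	Mgam
2678	0.000007	10812943	Pde4d
2686	0.000007	10927900	Sdpr
3647	0.0000592	10739323	Slc16a6
3981	0.0001	10765801	Crp
4508	0.0003	10768726	Npl
4834	0.0004	10755890	Spidr
5928	0.0012	10747948	Gfap
6811	0.0027	10826249	Vcam1
7018	0.0032	10858626	Cd163
7129	0.0035	10706326	Nkg7
8997	0.0116	10858886	Vwf
9093	0.0121	10886031	Fos
9599	0.0154	10881850	Park7
9657	0.0158	10832441	S100b
10160	0.0201	10765212	F5
10969	0.0276	10936899	Cybb
	NS	10709875	Adm
	NS	10802980	Mbp
	NS	10873895	Nppb
	NS	10859799	Il6
	NS	10922871	Il18r1
	NS	10921195	Aplp2
	NS	10702214	Arg1
	NS	10865502	Eno2
	NS	10727429	Gstp1
	NS	10746276	Nme1
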