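rank	p	probe_id	gene
182	1.99E-15	10818326	Sort1
1049	1.99E-09	10809392	Mt1a
1754	1.96E-07	10841850	Plcg1
1994	6.67E-07	10724895	Lyve1
2703	7.25E-06	10730855	Mxi1
4685	0.0003	10831567	RT1-Bb
6406	0.0019	10806650	Rad23a
6787	0.0027	10716436	Slc18a2
8839	0.0106	10940577	Itgb3
8997	0.0116	10858886	Vwf
10727	0.0252	10790948	Jund
12554	0.0496	10783998	Mcpt1
	NS	10742194	Pttg1
	NS	10900212	Tbxa2r
	NS	10885015	Frmd6
	NS	10894108	Vom2r53
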