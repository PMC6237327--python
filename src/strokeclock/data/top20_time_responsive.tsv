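p	probe_id	gene
1.83E-24	10722208	Mrgprx3
6.23E-22	10736312	Nos2
1.5E-21	10826956	Bank1
3.55E-21	10763768	Fcmr
4.77E-21	10748273	Cd79b
9.45E-21	10707142	Ldhc
1.28E-20	10922816	Il1r2
1.39E-20	10909411	Usp2
1.87E-20	10783880	Tgm1
2.46E-20	10826703	LOC691931
3.08E-20	10828832	Rab44
3.41E-20	10705065	Cd79a
6.38E-20	10721261	Cd33
7.1E-20	10893918	Sbno2
7.34E-20	10732941	Ebf1
7.38E-20	10864433	Prok2
8.69E-20	10728883	Ms4a1
1.5E-19	10823363	P2ry13
1.73E-19	10810144	Rrm2
1.84E-19	10892472	Igd
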