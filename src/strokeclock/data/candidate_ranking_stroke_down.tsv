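rank	p	probe_id	gene
291	3.59E-14	10802013	Cd74
683	6.75E-11	10798027	Ly86
727	1.11E-10	10718591	Myadm
869	4.66E-10	10895581	LOC689014
939	7.82E-10	10899387	Nr4a1
1277	1.27E-08	10861736	Akr1b1
1875	4.00E-07	10800760	Bin1
2110	1.16E-06	10711852	Ptpre
2664	6.56E-06	10910668	Anp32a
2899	1.18E-05	10716803	Utrn
3352	3.25E-05	10828357	Psmb9
3824	8.22E-05	10799241	Idi1
5939	0.0013	10890024	Nfkbia
6069	0.0014	10758705	Erp29
6248	0.0017	10726758	Irf7
7758	0.0056	10714106	Fam111a
9161	0.0125	10907315	Cela1
9823	0.0173	10790581	LOC290595
10478	0.0228	10775141	Rpap2
	NS	10863045	AABR07051563.1
	NS	10864893	Akr1b1-ps2
	NS	10929820	Ilkap
	NS	10804774	Adrb2
	NS	10811739	Chmp1a
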