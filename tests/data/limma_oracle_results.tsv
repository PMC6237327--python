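gene_id	F	p	s2_post
g001_A	2.8046961932114215e+01	4.2496531986292641e-13	9.0776565591796435e-02
g002_B	3.2844516843024486e+01	2.5886919080424489e-14	9.4241959513483728e-02
g003_C	2.3253315731812307e+01	1.0091978804964590e-11	1.1413815025611765e-01
g004_D	4.2727894098444068e+01	1.9299134520512409e-16	1.0158608116234684e-01
g005_E	4.0116946187502570e+01	6.4034100226508125e-16	5.6739968633432489e-02
g006_F	4.6449921241792595e+01	3.8519998843053110e-17	4.9881272102530315e-02
g007_G	5.9698770838442911e+01	2.6358895869731493e-19	4.7009213308503821e-02
g008_H	1.1254270452735582e+02	4.1686009798071944e-25	4.1141558932258536e-02
g009_A	8.7298263370927756e+01	9.8240346607780076e-23	3.1339291944900462e-02
g010_B	3.6234625496337181e+01	4.2950949319030560e-15	6.6994640809123165e-02
g011_C	5.5693468713369732e+01	1.0686073421875915e-18	5.8682266451389603e-02
g012_D	2.8168343252558472e+01	3.9425913481966106e-13	8.8124591683790568e-02
g013_E	1.6743604003425819e+01	1.6639868955057842e-09	1.3898556040881405e-01
g014_F	2.5893421757840873e+01	1.6746428432320137e-12	1.1861268500722261e-01
g015_G	5.1067231860014964e+01	6.0070823737526762e-18	5.8487322121051351e-02
g016_H	2.3329061646052605e+02	3.6624572798416125e-32	2.2690642534043407e-02
g017_A	8.9252236320921469e+01	6.1354518386359921e-23	3.6722667727220201e-02
g018_B	1.5240978937452098e+02	5.2771505831111331e-28	2.0058763837774163e-02
g019_C	5.3025503101842077e+01	2.8482611967060084e-18	4.4944526603013985e-02
g020_D	8.7796096457625126e+01	8.7059351019553905e-23	4.1652316761186976e-02
g021_NULL	2.8510670861265408e-01	9.1895550343087207e-01	4.6166253814582350e-02
g022_NULL	5.4733927116482617e-01	7.3947225122857119e-01	2.4383722614872011e-02
g023_NULL	1.1756233568117707e+00	3.3517422587215134e-01	4.7854683151350295e-02
g024_NULL	1.5337420914674440e+00	1.9739497994556374e-01	8.1929920839961604e-02
g025_NULL	9.0458378507734014e-02	9.9337525808094118e-01	9.7533210457535921e-02
g026_NULL	1.5893231708722175e+00	1.8136267715783813e-01	9.2578125704872324e-02
g027_NULL	4.1851282666420869e-01	8.3351453314785262e-01	3.8454513930939856e-02
g028_NULL	3.7627295034285291e-01	8.6246715727229251e-01	3.7990055618320612e-02
g029_NULL	1.0492455978880537e+00	4.0023207204539057e-01	3.4372245563351507e-02
g030_NULL	8.1249385497915438e-01	5.4671731038813842e-01	7.7829135912353312e-02
g031_NULL	9.8221686602667790e-01	4.3850636158948419e-01	5.5363883984317699e-02
g032_NULL	8.5184067778185979e-01	5.2026623565389296e-01	4.5377140371671607e-02
g033_NULL	4.4132557750349710e-01	8.1736441461769338e-01	1.7408784692725823e-01
g034_NULL	4.1050767379037967e-01	8.3910380027594567e-01	6.8461766957885445e-02
g035_NULL	5.0174930247048688e-01	7.7337249900578742e-01	3.0468780599257450e-02
g036_NULL	1.1081315428477021e+00	3.6876851324550414e-01	5.3210081757545165e-02
g037_NULL	1.6091308380017404e+00	1.7594785065418689e-01	2.2591705496354461e-02
g038_NULL	6.8945136457722445e-01	6.3383720698013279e-01	1.0861790420713062e-01
g039_NULL	1.1125262948750088e+00	3.6650121085413523e-01	1.2629058610422730e-01
g040_NULL	2.1764376178179261e+00	7.2520058130408391e-02	1.3088282089170369e-01
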