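id	coordinates	cpm	fc	pvalue	fdr
Cys-GCA	chr1:93981834-93981906	143.2	5.6	7.64E-08	7.96E-07
Tyr-GTA	chr2:27273650-27273738	113.6	4.0	6.20E-06	4.46E-05
Ala-TGC	chr6:28726141-28726212	189.6	3.5	1.31E-08	1.58E-07
Lys-CTT	chr16:3225692-3225764	1540.0	-3.4	4.95E-11	8.13E-10
Arg-CCG	chr17:66016013-66016085	138.3	-3.9	7.20E-06	5.00E-05
Arg-CCG	chr6:28849165-28849237	129.4	-3.9	5.07E-09	6.33E-08
Arg-CCG	chr15:79152904-79152976	8332.2	-4.0	5.43E-16	2.00E-14
Glu-TTC	chr13:45492062-45492133	2948.1	-4.1	8.19E-16	2.84E-14
Glu-TTC	chr14:58706613-58706685	3533.9	-4.3	3.52E-14	1.10E-12
Glu-TTC	chr16:3241501-3241573	7938.2	-4.5	3.12E-16	1.22E-14
Glu-TTC	chr16:3207406-3207478	374.3	-4.6	2.34E-08	2.71E-07
Val-TAC	chr6:27258405-27258477	582.8	-4.6	3.99E-07	3.72E-06
Val-TAC	chr2:131094701-131094772	612.6	-4.6	8.66E-17	3.61E-15
Val-CAC	chr5:180649395-180649467	10608.0	-5.0	7.75E-10	1.03E-08
Glu-CTC	chr6:28949976-28950047	14851.5	-5.0	6.09E-24	9.52E-22
Glu-CTC	chr1:161431809-161431880	3246.5	-5.0	1.63E-24	4.07E-22
Glu-CTC	chr13:41634874-41634945	591.9	-5.0	2.14E-15	7.05E-14
Glu-CTC	chr1:161424398-161424469	3189.5	-5.0	8.06E-20	4.20E-18
Glu-CTC	chr1:161439189-161439260	3227.3	-5.1	1.85E-23	2.27E-21
Glu-CTC	chr19:4724647-4724719	1610.7	-5.1	1.29E-11	2.59E-10
Glu-CTC	chr1:249168447-249168518	14777.2	-5.2	1.95E-24	4.07E-22
Glu-CTC	chr5:180600650-180600722	39309.5	-5.3	4.09E-10	5.80E-09
Glu-CTC	chr6:126101393-126101464	3240.3	-5.3	3.56E-23	3.18E-21
Glu-CTC	chr6:26538282-26538354	38899.7	-5.4	1.56E-10	2.27E-09
Glu-CTC	chr1:145399233-145399304	3225.7	-5.4	1.45E-24	4.07E-22
Glu-CTC	chr1:161417018-161417089	3243.8	-5.4	2.18E-23	2.27E-21
Glu-CTC	chr5:180524070-180524142	38336.8	-5.8	1.35E-10	2.00E-09
Glu-CTC	chr5:180529253-180529325	10581.3	-5.9	8.73E-11	1.40E-09
Glu-CTC	chr1:149298555-149298627	10125.3	-6.0	2.66E-11	4.90E-10
Glu-CTC	chr1:149684088-149684161	10446.6	-6.1	3.98E-11	6.91E-10
Glu-CTC	chr15:26327381-26327452	2569.5	-6.2	6.61E-22	5.16E-20
Glu-CTC	chr1:161369490-161369562	10640.4	-6.3	4.74E-11	8.01E-10
Val-AAC	chr3:169490018-169490090	36234.5	-6.5	1.51E-11	2.96E-10
Trp-CCA	chr17:8089676-8089747	145.1	-6.6	4.53E-08	4.96E-07
Trp-CCA	chr5:180596610-180596682	37347.2	-6.6	1.11E-11	2.31E-10
Trp-CCA	chr5:180645270-180645342	9935.0	-6.6	1.79E-12	4.47E-11
Trp-CCA	chr6:27648885-27648957	10105.2	-6.6	1.05E-11	2.26E-10
Trp-CCA	chr5:180591154-180591226	37053.9	-6.7	5.06E-12	1.17E-10
Gly-CCC	chr1:17053780-17053850	151.8	-6.7	3.84E-11	6.85E-10
Gly-CCC	chr6:27721179-27721251	10156.5	-6.8	4.99E-12	1.17E-10
Gly-CCC	chr6:27618707-27618779	9941.2	-6.9	6.51E-12	1.45E-10
Gly-CCC	chr11:59318102-59318174	484.7	-8.2	2.03E-13	5.76E-12
Arg-TCT	chr1:94313129-94313213	3283.4	-10.0	3.88E-18	1.73E-16
Arg-TCT	chrX:18693029-18693101	459.1	-10.4	3.06E-19	1.47E-17
Arg-TCT	chr6:27248049-27248121	18754.0	-11.2	1.46E-12	3.81E-11
Arg-TCT	chr17:19411494-19411565	172.1	-12.6	9.25E-13	2.51E-11
Arg-TCT	chr6:27173867-27173939	215.8	-14.0	3.75E-14	1.12E-12
Arg-TCT	chr1:149294666-149294736	1407.1	-23.4	2.35E-21	1.63E-19
Arg-TCT	chr6:27203288-27203360	655.2	-24.4	5.65E-21	3.53E-19
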