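id	status	coordinates	cpm	fc	pvalue	fdr
chr3_6283	novel	chr3:53118889..53118935:+	7	6.8	1.19E-03	1.15E-02
chr17_28999	novel	chr17:75803646..75803705:+	7	5.5	9.79E-04	9.68E-03
chr6_12928	novel	chr6:11631870..11631921:-	7	4.5	2.63E-03	2.06E-02
chr8_16791	novel	chr8:56821958..56822010:-	7	4.2	5.35E-03	3.62E-02
chr7_15527	novel	chr7:142157355..142157408:-	8	-2.8	3.37E-04	4.94E-03
chr16_28195	novel	chr16:58762523..58762572:-	59	-2.8	3.03E-09	2.96E-07
chr9_17997	novel	chr9:133282130..133282175:+	1092	-3.1	1.92E-04	3.00E-03
hsa-miR-205-5p	known	chr1:209605511..209605569:+	16	4.3	3.22E-04	4.81E-03
hsa-miR-145-5p	known	chr5:148810224..148810285:+	13	2.2	5.81E-04	6.70E-03
hsa-miR-27b-5p	known	chr9:97847745..97847807:+	931	2.2	8.05E-05	1.65E-03
hsa-miR-103a-3p	known	chr5:167987912..167987968:-	856	2.0	2.24E-03	1.81E-02
hsa-miR-107	known	chr10:91352516..91352572:-	856	2.0	2.24E-03	1.81E-02
hsa-miR-320a	known	chr8:22102489..22102539:-	225	1.9	5.48E-04	6.61E-03
hsa-miR-320b	known	chr1:224444752..224444801:-	225	1.9	5.48E-04	6.61E-03
hsa-miR-486-5p	known	chr8:41517962..41518025:+	258635	1.9	5.01E-05	1.16E-03
hsa-miR-100-5p	known	chr11:122022947..122023004:-	185	1.9	1.39E-02	7.14E-02
hsa-miR-32-5p	known	chr9:111808511..111808573:-	26	1.9	3.05E-02	1.20E-01
hsa-miR-215-5p	known	chr1:220291218..220291278:-	33	1.8	2.76E-02	1.13E-01
hsa-miR-148a-5p	known	chr7:25989541..25989601:-	1310	1.8	1.54E-04	2.50E-03
hsa-miR-99a-5p	known	chr21:17911421..17911481:+	66	1.8	4.33E-02	1.49E-01
hsa-miR-191-5p	known	chr3:49058063..49058127:-	4948	-2.2	2.15E-08	1.89E-06
hsa-miR-26a-5p	known	chr3:38010904..38010965:+	3131	-2.4	1.01E-05	3.57E-04
hsa-miR-181a-5p	known	chr1:198828197..198828259:-	2673	-1.8	6.19E-05	1.33E-03
hsa-miR-150-5p	known	chr19:50004055..50004110:-	1839	-6.1	5.55E-08	4.44E-06
hsa-let-7f-5p	known	chr9:96938635..96938713:+	725	-2.2	6.34E-04	6.88E-03
hsa-miR-93-5p	known	chr7:99691398..99691460:-	712	-1.9	1.94E-03	1.66E-02
hsa-let-7a-5p	known	chr22:46508632..46508702:+	535	-2.1	1.11E-04	2.06E-03
hsa-miR-30c-5p	known	chr6:72086668..72086728:-	353	-3.4	9.28E-07	4.30E-05
hsa-miR-28-5p	known	chr3:188406582..188406644:+	352	-1.8	5.15E-04	6.57E-03
hsa-miR-26b-5p	known	chr2:219267380..219267436:+	188	-2.1	2.02E-07	1.37E-05
hsa-miR-30b-5p	known	chr8:135812774..135812834:-	86	-5.3	1.82E-14	5.34E-12
hsa-miR-122-5p	known	chr18:56118320..56118377:+	25	-3.9	9.65E-04	9.65E-03
hsa-miR-98-5p	known	chrX:53583201..53583281:-	20	-2.7	1.39E-05	4.40E-04
hsa-miR-183-5p	known	chr7:129414767..129414827:-	20	-2.1	4.15E-02	1.46E-01
hsa-miR-224-5p	known	chrX:151127056..151127123:-	16	-3.3	1.39E-03	1.30E-02
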