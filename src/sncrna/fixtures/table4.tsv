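id	end	coordinates	cpm	fc	pvalue	fdr
RNY1	5p	chr7:148684228-148684340	18001.3	4.2	2.70E-30	1.24E-20
RNY4P17	5p	chr4:169926400-169926495	198.7	2.5	1.34E-08	1.80E-08
RNY4P1	3p	chr9:77462422-77462517	4402.8	-2.1	4.57E-05	3.20E-06
RNY4P5	3p	chr8:124056957-124057052	4564.0	-2.1	3.08E-05	3.08E-06
RNY4P8	3p	chr17:38399475-38399571	4059.5	-2.2	4.93E-05	1.77E-06
RNY4P11	3p	chr20:18309650-18309746	4163.5	-2.2	3.52E-05	1.62E-06
Y_RNA.725	3p	chr9:72926523-72926617	198.5	-2.4	7.15E-08	5.96E-08
Y_RNA.122	5p	chr17:41149933-41150024	139.4	-2.5	2.54E-22	7.75E-08
RNY4P20	5p	chr6:151619976-151620068	1896.0	-2.5	3.61E-31	6.21E-09
RNY4P25	3p	chr1:151411476-151411571	407.5	-2.5	2.84E-07	9.28E-09
RNY4P27	5p	chr13:95988360-95988455	1290.9	-2.7	6.58E-29	2.75E-10
Y_RNA.182	3p	chr11:33025796-33025891	2049.6	-2.7	2.16E-07	1.59E-10
Y_RNA.257	3p	chr11:3685045-3685141	1575.3	-2.8	8.02E-08	5.43E-11
RNY4P18	3p	chr9:113859605-113859693	181.9	-2.8	2.14E-09	1.59E-10
Y_RNA.44	5p	chr22:41461558-41461650	195.9	-7.1	1.89E-82	1.42E-31
RNY4P6	5p	chr11:116886613-116886708	772.2	-7.2	8.69E-39	3.72E-35
Y_RNA.668	5p	chr11:118841208-118841305	216.4	-7.6	2.84E-85	1.79E-34
Y_RNA.7	5p	chr15:26063130-26063217	548.3	-10.8	1.45E-105	4.77E-48
Y_RNA.796	5p	chr2:201727875-201727970	536.7	-16.5	4.33E-114	1.74E-61
Y_RNA.292	3p	chr10:90345395-90345490	266.3	-100.3	1.39E-98	1.88E-106
Y_RNA.662	3p	chr2:122360649-122360740	153.7	-129.1	5.13E-90	4.09E-91
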