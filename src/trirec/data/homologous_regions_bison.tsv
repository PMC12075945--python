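region	start	end	length
1-gart-Bis	6481	8348	1868
2-tmem50b-Bis	22859	25875	3017
3-il10rb-Bis	24068	25872	1805
4-il10rb-Bis	15573	16759	1187
5-ifnar2-Bis	43219	44162	944
6-urb1-Bis	51345	54346	3002
7-grik1-Bis	147651	150567	2917
8-grik1-Bis	215970	216535	566
9-grik1-Bis	286116	288060	1945
10-grik1-Bis	359675	361233	1559
11-grik1-Bis	359675	361233	1559
12-grik1-Bis	466917	468534	1618
13-ltn1-Bis	40839	42607	1769
14-app-Bis	24343	27080	2738
15-app-Bis	164433	167183	2751
16-app-Bis	205433	206385	953
17-app-Bis	164433	166087	1655
18-app-Bis	164430	166591	2162
19-app-Bis	164433	166715	2283
20-jam2-Bis	76649	78816	2168
C1-kcne2-Bis	1569	3525	1957
C2-grik1-Bis	110695	113631	2937
C3-grik1-Bis	286114	287632	1519
C4-grik1-Bis	276452	278785	2334
C5-usp16-Bis	23727	24125	399
C6-cyyr1-Bis	27214	29161	1948
C7-app-Bis	238752	241966	3215
C8-app-Bis	164412	166018	1607
C9-app-Bis	164769	165870	1102
C10-jam2-Bis	75734	78221	2488
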