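gene	species	chrom	start	end	length	strand
kcne2	cattle	chr1	460824	468632	7809	C
gart	cattle	chr1	1064795	1091084	26290	+
tmem50b	cattle	chr1	1125432	1162271	36840	+
il10rb	cattle	chr1	1364073	1392682	28610	C
ifnar2	cattle	chr1	1394236	1428725	34490	C
urb1	cattle	chr1	2181487	2258468	76982	+
grik1	cattle	chr1	5245035	5717636	472602	+
usp16	cattle	chr1	6365264	6391124	25861	C
ltn1	cattle	chr1	6419776	6476700	56925	+
cyyr1	cattle	chr1	9186471	9301517	115047	+
app	cattle	chr1	9540541	9909501	368961	+
jam2	cattle	chr1	10014214	10096812	82599	C
kcne2	bison	NW_011495041.1	438216	446126	7911	C
gart	bison	NW_011495041.1	1304517	1331783	27267	+
tmem50b	bison	NW_011495041.1	1366487	1403341	36855	+
il10rb	bison	NW_011495041.1	1605601	1634436	28836	C
ifnar2	bison	NW_011495041.1	1635891	1701341	65451	C
urb1	bison	NW_011495041.1	2425279	2503498	78220	+
grik1	bison	NW_011494940.1	3737498	4211412	473915	C
usp16	bison	NW_011494776.1	270105	296092	25988	C
ltn1	bison	NW_011494776.1	326250	385753	59504	+
cyyr1	bison	NW_011494666.1	1283391	1406400	123010	+
app	bison	NW_011494666.1	1653242	1966900	313659	+
jam2	bison	NW_011494666.1	2127848	2211323	83476	C
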