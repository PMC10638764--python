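chrom	start	end	length	genes
16	33344230	33431230	87000	TP53TG3,TP53TG3C,LOC105369266,TP53TG3F,TP53TG3E,TP53TG3B,LOC102723655
8	130277390	130287390	10000	ASAP1
8	128206232	128325232	119000
8	127997937	128120937	123000	MIR1207,PVT1,MIR1206
16	33293089	33296089	3000
6	256190	383190	127000	DUSP22
8	128121842	128204842	83000	MIR1208
16	32296519	32301519	5000
8	127816213	127993213	177000	PVT1,TMEM75,MIR1205
16	32349447	32371447	22000
8	135017057	135020057	3000
16	33239097	33242097	3000
8	127437402	127813402	376000	PVT1,MYC,CASC11,CASC8,MIR1204
22	24665296	24668296	3000
8	128332468	128392468	60000
15	20459784	20462784	3000	HERC2P3
8	128393562	129010562	617000	LINC00976,LINC00824
13	28381083	28555083	174000	FLT1
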