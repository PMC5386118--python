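state	cytoband	start	end	genes
+	8q21.3	90,709,838	92,033,734	NECAB1, CALB1, DECR1, NBN, OSGIN2 (C8orf1), RIPK2, TMEM64 (DFKZp762C1112)
+	8q22.1-22.2	99,007,325	100,014,623	C8orf47, NIPAL2, HRSP12, KCNS2, MATN2, POP1, RPL30, STK3
+	8q24.11	118,393,066	118,844,178	MED30 (THRAP6)
+	8q24.3	140,665,174	140,805,057	KCNK9
+	12p12.1	22,535,457	24,308,820	C2CD5 (KIAA0528), ETNK1, SOX5
+	12q12	40,876,491	42,688,707	ADAMTS20, TMEM117, IRAK4, PPHLN1, PRICKLE1, PUS7L (DKFZP434G1415), TWF1 (PTK9), YAF2, ZCRB1 (MADP-1)
+	13q13.3	37,635,092	38,496,395	UFM1, FREM2, STOML3, PROSER1
+	13q21.2	58,572,030	60,726,339	DIAPH3, TDRD3
+	13q22.1	72,583,695	73,033,999	-
+	13q22.2	74,725,315	74,918,459	TBC1D4
+	13q31.1	84,731,597	85,139,789	-
+	13q31.3	90,532,984	91,293,729	GPC5
+	13q33.1-33.2	103,314,852	104,473,863	-
+	20q13.13-13.2	47,868,388	49,291,771	KCNG1, ADNP, BCAS4, CEBPB, DPM1, FAM65C (C20orf175), MOCS3, PARD6B, PTPN1, RNF114 (ZNF313), SNAI1, SPATA2, TMEM189 (Kua), TMEM189-UBE2V1 (Kua-UEV), UBE2V1, SLC9A8
-	8p22	13,833,679	14,445,035	SGCZ
-	18p11.23	7,579,318	7,816,623	PTPRM
-	18p11.21	12,535,581	14,045,454	SPIRE1, PSMG2, CEP76, PTPN2, SEH1L, CEP192, LDLRAD4, FAM210A, RNMT, MC5R, MC2R
-	18q12.1	25,987,928	27,146,504	DSC3, DSC2, DSC1
-	18q23	71,882,399	74,199,087	ZNF516, FLJ44313, FLJ44881, ZNF236, MBP, GALR1
-	22q11.1-11.21	15,685,581	16,590,946	CECR2, GAB4, ATP6V1E1, BCL2L13, CECR1, CECR5, CECR6, IL17RA, SLC25A18, CECR3, CECR7, IGKV1-12
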