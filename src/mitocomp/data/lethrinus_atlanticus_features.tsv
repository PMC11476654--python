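name	cls	strand	start	stop	size	in	start_codon	stop_codon	anticodon
tRNA-Phe (F)	tRNA	+	1	68	68	0			TTC
12S rRNA	rRNA	+	69	1024	956	0			
tRNA-Val (V)	tRNA	+	1025	1098	74	0			GTA
16S rRNA	rRNA	+	1099	2899	1801	0			
tRNA-Leu (L2)	tRNA	+	2900	2973	74	0			TTA
ND1	PCG	+	2974	3945	972	4	ATG	TAG	
tRNA-Ile (I)	tRNA	+	3950	4019	70	-1			ATC
tRNA-Gln (Q)	tRNA	-	4019	4089	71	-1			CAA
tRNA-Met (M)	tRNA	+	4089	4158	70	0			ATG
ND2	PCG	+	4159	5204	1046	0	ATG	TA-	
tRNA-Trp (W)	tRNA	+	5205	5277	73	0			TGA
tRNA-Ala (A)	tRNA	-	5278	5346	69	1			GCA
tRNA-Asn (N)	tRNA	-	5348	5420	73	37			AAC
tRNA-Cys (C)	tRNA	-	5458	5526	69	0			TGC
tRNA-Tyr (Y)	tRNA	-	5527	5596	70	1			TAC
COI	PCG	+	5598	7148	1551	1	GTG	TAA	
tRNA-Ser (S2)	tRNA	-	7150	7220	71	3			TCA
tRNA-Asp (D)	tRNA	+	7224	7295	72	7			GAC
COII	PCG	+	7303	7993	691	0	ATG	T--	
tRNA-Lys (K)	tRNA	+	7994	8068	75	1			AAA
ATP8	PCG	+	8070	8237	168	13	ATG	TAA	
ATP6	PCG	+	8251	8933	683	0	ATG	TA-	
COIII	PCG	+	8934	9718	785	0	ATG	TA-	
tRNA-Gly (G)	tRNA	+	9719	9790	72	0			GGA
ND3	PCG	+	9791	10139	349	0	ATG	T--	
tRNA-Arg (R)	tRNA	+	10140	10208	69	0			CGA
ND4L	PCG	+	10209	10505	297	-7	ATG	TAA	
ND4	PCG	+	10499	11879	1381	0	ATG	T--	
tRNA-His (H)	tRNA	+	11880	11948	69	0			CAC
tRNA-Ser (S1)	tRNA	+	11949	12018	70	4			AGC
tRNA-Leu (L1)	tRNA	+	12023	12095	73	0			CTA
ND5	PCG	+	12096	13934	1839	-4	ATG	TAA	
ND6	PCG	-	13931	14452	522	0	ATG	TAG	
tRNA-Glu (E)	tRNA	-	14453	14521	69	4			GAA
CYTB	PCG	+	14526	15666	1141	0	ATG	T--	
tRNA-Thr (T)	tRNA	+	15667	15738	72	-1			ACA
tRNA-Pro (P)	tRNA	-	15738	15806	69	0			CCA
Control region	CR	+	15807	16789	983	0			
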