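name	class	start	end	strand_sense	complex
mtCTR	control	16024	576	light	none
HVS1	HVS	16024	16383	light	none
HVS2	HVS	57	372	light	none
HVS3	HVS	438	574	light	none
OriH	origin	191	191	light	none
OriL	origin	5721	5798	light	none
MT-RNR1	rRNA	648	1601	light	none
MT-RNR2	rRNA	1671	3229	light	none
MT-ND1	protein	3307	4262	light	I
MT-ND2	protein	4470	5511	light	I
MT-CO1	protein	5904	7445	light	IV
MT-CO2	protein	7586	8269	light	IV
MT-ATP8	protein	8366	8572	light	V
MT-ATP6	protein	8527	9207	light	V
MT-CO3	protein	9208	9990	light	IV
MT-ND3	protein	10059	10404	light	I
MT-ND4L	protein	10470	10766	light	I
MT-ND4	protein	10760	12137	light	I
MT-ND5	protein	12337	14148	light	I
MT-ND6	protein	14149	14673	heavy	I
MT-CYB	protein	14747	15887	light	III
MT-TF	tRNA	577	647	light	none
MT-TV	tRNA	1602	1670	light	none
MT-TL1	tRNA	3230	3304	light	none
MT-TI	tRNA	4263	4331	light	none
MT-TQ	tRNA	4329	4400	heavy	none
MT-TM	tRNA	4402	4469	light	none
MT-TW	tRNA	5512	5579	light	none
MT-TA	tRNA	5587	5655	heavy	none
MT-TN	tRNA	5657	5729	heavy	none
MT-TC	tRNA	5761	5826	heavy	none
MT-TY	tRNA	5826	5891	heavy	none
MT-TS1	tRNA	7446	7514	heavy	none
MT-TD	tRNA	7518	7585	light	none
MT-TK	tRNA	8295	8364	light	none
MT-TG	tRNA	9991	10058	light	none
MT-TR	tRNA	10405	10469	light	none
MT-TH	tRNA	12138	12206	light	none
MT-TS2	tRNA	12207	12265	light	none
MT-TL2	tRNA	12266	12336	light	none
MT-TE	tRNA	14674	14742	heavy	none
MT-TT	tRNA	15888	15953	light	none
MT-TP	tRNA	15956	16023	heavy	none
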