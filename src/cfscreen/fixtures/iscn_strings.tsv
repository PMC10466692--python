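raw	chromosome	category	karyotype	mosaic
arr[GRCh37] 21q11.2q22.3(15,016,486_48,093,361)×3	chr21	T21		False
arr[GRCh37] 21q21.3q22.3(28,054,301_48,093,361)×2–3	chr21	CNV_DUP		True
arr[GRCh37]18p11.32q23(136,227_78,013,728)×3	chr18	T18		False
arr[GRCh37]13q12.2q32.3(28,722,472_100,577,274)×3	chr13	T13		False
arr[GRCh37] Xp22.33q28(168,551_155,233,098)×1	chrX	SCA	45,X	False
arr[GRCh37] Xp22.33q28(168,551_155,233,098)×2	chrX	SCA	47,XXY	False
arr[GRCh37] Xp22.33q28(168,551_155,233,098)×3	chrX	SCA	47,XXX	False
arr[GRCh37] Xp22.33q28(168,551_155,233,098)×1_2	chrX	SCA	45,X	True
arr[GRCh37] Xp22.33q28(168,551_155,233,098)×1–3	chrX	SCA	45,X	True
arr[GRCh37] Xp22.33q22.1(168,551_98,064,447)×1–2	chrX	CNV_DEL		True
arr[GRCh37] Xq22.1q28(98,064,447_155,233,098)×1	chrX	CNV_DEL		False
arr[GRCh37]Xq23q28(110,557,268_155,233,098)×1	chrX	CNV_DEL		False
arr[GRCh37]9p24.3q13(208,454_68,342,770)×3	chr9	CNV_DUP		False
arr[GRCh37] Yp11.2q11.23(5,997,807_28,799,653)×0	chrY	SCA	45,X	False
arr[GRCh37] Yp11.31p11.2(2,650,424_9,172,827)×2	chrY	CNV_DUP		False
arr[GRCh37] Yp11.2q11.23(9,329,329_28,799,654)×2	chrY	SCA	47,XYY	False
arr[GRCh37]] 2p25.3q37.3(12,770_242,524,587)×2–3	chr2	RAT		True
arr[GRCh37] 7p22.3q36.3(43,376_159,119,707)×2–3	chr7	RAT		True
arr[GRCh37]16p13.3q24.3(85,880_90,155,062)×2–3	chr16	RAT		True
arr[GRCh37]22q11.1q13.33(16,888,899_51,197,766)×2–3	chr22	RAT		True
arr[GRCh37]20p13q13.33(61,661_62,913,645)×2–3	chr20	RAT		True
arr[GRCh37]10q25.3q26.12(116,585,858_122,530,451)×1	chr10	CNV_DEL		False
45,XO	chrX	SCA	45,X	False
47,XXY	chrX	SCA	47,XXY	False
47,XXX	chrX	SCA	47,XXX	False
47,XYY	chrY	SCA	47,XYY	False
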