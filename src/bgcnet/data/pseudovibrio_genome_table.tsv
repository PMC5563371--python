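species	strain	length_bp	gc_percent	n_fragments	accession
Pseudovibrio ascidiaceicola	DSM 16392 (F423)	5845495	49.76	45	FOSK00000000.1
Pseudovibrio axinellae	AD2	5126200	50.3	162	LMCB00000000.1
Pseudovibrio sp.	AD5	6061014	49.87	66	LMCH00000000.1
Pseudovibrio sp.	W64 (AD8)	5935921	50.13	49	LMCI00000000.1
Pseudovibrio sp.	AD13	6001312	50.64	36	LMCC00000000.1
Pseudovibrio sp.	AD14	6201736	50.02	57	LMCD00000000.1
Pseudovibrio sp.	W74 (AD15)	6190724	50.29	64	LMCJ00000000.1
Pseudovibrio sp.	AD26	6181400	45.17	159	LMCE00000000.1
Pseudovibrio sp.	WM33 (AD30)	5745729	51.02	159	LMCK00000000.1
Pseudovibrio sp.	AD37	5875058	50	224	LMCF00000000.1
Pseudovibrio sp.	AD46	6124061	49.79	85	LMCG00000000.1
Pseudovibrio denitrificans	DSM 17465	6080381	52.2	36	FPBD00000000.1
Pseudovibrio denitrificans	JCM 12308	6053738	52.2	94	BAZK00000000.1
Pseudovibrio hongkongensis	MCCC 1K00451 (UST20140214-015B)	3746600	51.68	39	LLWC00000000.1
Pseudovibrio stylochi	MCCC 1K00452 (UST20140214-052)	3682052	46.16	46	LLWE00000000.1
Pseudovibrio sp.	MIEL01 (AB134)	5975630	52.1	39	MIEL00000000.1
Pseudovibrio sp.	FO-BEG1	5916782	52.5	2	CP003147.1;CP003148.1
Pseudovibrio sp.	JCM 19062	4607025	51.02	286	BAXV00000000.1
Pseudovibrio sp.	JE062	5717078	52.15	53	ABXL00000000.1
Pseudovibrio sp.	POLY-S9 (PPL9)	6559398	50.57	163	LCWX00000000.1
Pseudovibrio sp.	Tun.PHSC04-5.I4	6549844	50.49	8	FNLB00000000.1
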