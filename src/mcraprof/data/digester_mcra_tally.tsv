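species	accession	order	metabolism	hits
Methanosaeta concilii GP-6	CP002565.1	Methanosarcinales	1	946
No significant similarity found		NA	NA	262
Methanosaeta concilii VeAc9	AF313803.1	Methanosarcinales	1	140
Methanobacterium kanagiense 169	AB551869.1	Methanobacteriales	2	84
Methanobacterium formicicum DSM 1535	EF465108.1	Methanobacteriales	2*	73
Methanospirillum hungatei JF-1	CP000254.1	Methanomicrobiales	2*	55
Methanobacterium formicicum NBRC 100475	AB542750.1	Methanobacteriales	2*	51
Methanosaeta harundinacea 8Ac	AY970348.1	Methanosarcinales	1	48
Methanolinea sp. TNR	AB496719.1	Methanomicrobiales	2*	44
Methanosarcina mazei strain MT	AY260440.1	Methanosarcinales	1, 2, 3	43
Methanobacterium subterraneum NBRC 105231	AB542754.1	Methanobacteriales	2	35
Methanoregula formicicum SMSP	AB479391.1	Methanomicrobiales	2*	22
Methanoculleus palmolei	AB300784.1	Methanomicrobiales	2*, 3	12
Methanosarcina sp. HB-1	AB288266.1	Methanosarcinales	1, 2	12
Methanobacterium ivanovii NBRC 104952	AB542751.1	Methanobacteriales	2	8
Methanobacterium formicicum S1 mrtA	EF465103.1	Methanobacteriales	2*	6
Methanogenium organophilum	AB353222.1	Methanomicrobiales	2*	6
Methanoculleus thermophilus	AB300783.1	Methanomicrobiales	2*	5
Methanosarcina thermophila	AB353225.1	Methanosarcinales	1, 2	5
Methanobacterium uliginosum DSM 2956 mrtA	EF465105.1	Methanobacteriales	2	5
Methanosarcina mazei	EF452663.1	Methanosarcinales	1, 2, 3	4
Methanobacterium ferruginis	AB542745.1	Methanobacteriales	2	3
Methanobacterium petrolearium	AB542744.1	Methanobacteriales	2	3
Methanoculleus marisnigri JR1	CP000562.1	Methanomicrobiales	2*	3
Methanolinea tarda	AB300466.1	Methanomicrobiales	2*	3
Methanosarcina mazei LYC	AB300782.1	Methanosarcinales	1, 2, 3	3
Methanosarcina sp. T36	AB288292.1	Methanosarcinales	1, 2, 3	3
Methanobacterium sp. GH	HM802935.1	Methanobacteriales	2	2
Methanosaeta concilii DSM 3671	AF313802.1	Methanosarcinales	1	2
Methanosaeta thermophila PT	CP000477.1	Methanosarcinales	1	2
Methanospirillum lacunae	AB517988.1	Methanomicrobiales	2*	2
Methanobacterium palustre NBRC 105230	AB542753.1	Methanobacteriales	2*	1
Methanoculleus chikugoensis	AB288270.1	Methanomicrobiales	2*, 3	1
Methanosaeta harundinacea	HQ188223.1	Methanosarcinales	1	1
Methanothermobacter thermautotrophicus	AE000666.1	Methanobacteriales	2*	1
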