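species	strain	subgenus	group	subgroup	seq_method	te_percent
D. albomicans		Drosophila	immigrans	nasuta	NGS	2.73
D. buzzatii	st-1	Drosophila	repleta	mulleri	NGS	5.99
D. buzzatii	j-19	Drosophila	repleta	mulleri	NGS	2.40
D. mojavensis		Drosophila	repleta	mulleri	Sanger	16.14
D. americana	H5	Drosophila	virilis	virilis	NGS	9.11
D. virilis		Drosophila	virilis	virilis	Sanger	17.51
D. grimshawi		Hawaian	grimshawi	grimshawi	Sanger	15.86
D. ananassae		Sophophora	melanogaster	ananassae	Sanger	30.33
D. bipectinata		Sophophora	melanogaster	ananassae	NGS	16.94
D. elegans		Sophophora	melanogaster	elegans	NGS	12.05
D. eugracilis		Sophophora	melanogaster	eugracilis	NGS	13.67
D. ficusphila		Sophophora	melanogaster	ficusphila	NGS	9.45
D. erecta		Sophophora	melanogaster	melanogaster	Sanger	14.41
D. melanogaster		Sophophora	melanogaster	melanogaster	Sanger	21.67
D. sechellia		Sophophora	melanogaster	melanogaster	Sanger	20.90
D. simulans	r1.3	Sophophora	melanogaster	melanogaster	Sanger	11.85
D. simulans	r2.01	Sophophora	melanogaster	melanogaster	NGS	8.44
D. yakuba		Sophophora	melanogaster	melanogaster	Sanger	21.98
D. kikkawai		Sophophora	melanogaster	montium	NGS	11.95
D. rhopaloa		Sophophora	melanogaster	rhopaloa	NGS	18.62
D. biarmipes		Sophophora	melanogaster	suzukii	NGS	14.48
D. suzukii		Sophophora	melanogaster	suzukii	NGS	18.70
D. takahashii		Sophophora	melanogaster	takahashii	NGS	14.68
D. miranda		Sophophora	obscura	obscura	NGS	5.47
D. persimilis		Sophophora	obscura	obscura	Sanger	23.97
D. pseudoobscura		Sophophora	obscura	obscura	Sanger	12.68
D. willistoni		Sophophora	willistoni	willistoni	Sanger	24.39
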