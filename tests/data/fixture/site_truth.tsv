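chrom	pos	strand	region	context	gene
chr1	150	+	five_prime_utr	CGGGA	GA
chr1	250	+	cds	CGGGG	GA
chr1	500	+	intron	CAGAG	GA
chr1	800	+	three_prime_utr	CAGGG	GA
chr1	1950	-	five_prime_utr	CCAGG	GB
chr1	1400	-	cds	CGGGA	GB
chr1	1600	-	intron	CTGGG	GB
chr1	1250	-	three_prime_utr	CGGGG	GB
chr2	400	+	cds	CGGGA	GC
chr2	1500	+	unassigned	CGGGG	
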