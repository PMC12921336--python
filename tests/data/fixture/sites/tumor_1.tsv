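chrom	pos	strand	coverage	methylated	meth_rate	gene
chr1	150	+	98	77	0.7857143	GA
chr1	250	+	80	71	0.8875	GA
chr1	500	+	33	22	0.6666667	GA
chr1	800	+	53	30	0.5660377	GA
chr1	1250	-	70	46	0.6571429	GB
chr1	1400	-	77	76	0.987013	GB
chr1	1600	-	33	25	0.7575758	GB
chr1	1950	-	64	47	0.734375	GB
chr2	400	+	20	17	0.85	GC
chr2	1500	+	42	24	0.5714286	
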