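chrom	pos	strand	coverage	methylated	meth_rate	gene
chr1	150	+	68	26	0.3823529	GA
chr1	250	+	61	10	0.1639344	GA
chr1	500	+	82	27	0.3292683	GA
chr1	800	+	59	39	0.6610169	GA
chr1	1250	-	68	15	0.2205882	GB
chr1	1400	-	76	35	0.4605263	GB
chr1	1600	-	65	26	0.4	GB
chr1	1950	-	81	14	0.1728395	GB
chr2	400	+	67	24	0.358209	GC
chr2	1500	+	84	11	0.1309524	
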