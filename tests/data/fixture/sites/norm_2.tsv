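chrom	pos	strand	coverage	methylated	meth_rate	gene
chr1	150	+	32	2	0.0625	GA
chr1	250	+	97	23	0.2371134	GA
chr1	500	+	62	2	0.03225806	GA
chr1	800	+	81	22	0.2716049	GA
chr1	1250	-	23	1	0.04347826	GB
chr1	1400	-	99	41	0.4141414	GB
chr1	1600	-	89	17	0.1910112	GB
chr1	1950	-	84	7	0.08333333	GB
chr2	400	+	96	29	0.3020833	GC
chr2	1500	+	32	6	0.1875	
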