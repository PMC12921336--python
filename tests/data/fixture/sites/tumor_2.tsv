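chrom	pos	strand	coverage	methylated	meth_rate	gene
chr1	150	+	24	20	0.8333333	GA
chr1	250	+	49	19	0.3877551	GA
chr1	500	+	28	26	0.9285714	GA
chr1	800	+	71	58	0.8169014	GA
chr1	1250	-	34	16	0.4705882	GB
chr1	1400	-	24	19	0.7916667	GB
chr1	1600	-	81	75	0.9259259	GB
chr1	1950	-	49	21	0.4285714	GB
chr2	400	+	14	10	0.7142857	GC
chr2	1500	+	44	34	0.7727273	
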