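chr1	morgan5c	exon	101	400	.	+	.	gene_name "GA"; transcript_id "tx1";
chr1	morgan5c	exon	601	900	.	+	.	gene_name "GA"; transcript_id "tx1";
chr1	morgan5c	CDS	201	400	.	+	.	gene_name "GA"; transcript_id "tx1";
chr1	morgan5c	CDS	601	700	.	+	.	gene_name "GA"; transcript_id "tx1";
chr1	morgan5c	exon	1201	1500	.	-	.	gene_name "GB"; transcript_id "tx2";
chr1	morgan5c	exon	1701	2000	.	-	.	gene_name "GB"; transcript_id "tx2";
chr1	morgan5c	CDS	1301	1500	.	-	.	gene_name "GB"; transcript_id "tx2";
chr1	morgan5c	CDS	1701	1900	.	-	.	gene_name "GB"; transcript_id "tx2";
chr2	morgan5c	exon	101	1000	.	+	.	gene_name "GC"; transcript_id "tx3";
chr2	morgan5c	CDS	301	800	.	+	.	gene_name "GC"; transcript_id "tx3";
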