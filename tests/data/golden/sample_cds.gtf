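chr1	isoforge	exon	201	449	.	+	.	gene_id "GENA"; transcript_id "PB.1.1";
chr1	isoforge	exon	570	764	.	+	.	gene_id "GENA"; transcript_id "PB.1.1";
chr1	isoforge	exon	909	1172	.	+	.	gene_id "GENA"; transcript_id "PB.1.1";
chr1	isoforge	exon	1278	1520	.	+	.	gene_id "GENA"; transcript_id "PB.1.1";
chr1	isoforge	exon	1629	1895	.	+	.	gene_id "GENA"; transcript_id "PB.1.1";
chr1	isoforge	exon	1995	2249	.	+	.	gene_id "GENA"; transcript_id "PB.1.1";
chr1	isoforge	CDS	579	764	.	+	.	gene_id "GENA"; transcript_id "PB.1.1";
chr1	isoforge	CDS	909	1172	.	+	.	gene_id "GENA"; transcript_id "PB.1.1";
chr1	isoforge	CDS	1278	1520	.	+	.	gene_id "GENA"; transcript_id "PB.1.1";
chr1	isoforge	CDS	1629	1895	.	+	.	gene_id "GENA"; transcript_id "PB.1.1";
chr1	isoforge	CDS	1995	2204	.	+	.	gene_id "GENA"; transcript_id "PB.1.1";
chr1	isoforge	exon	570	764	.	+	.	gene_id "GENA"; transcript_id "PB.1.2";
chr1	isoforge	exon	909	1172	.	+	.	gene_id "GENA"; transcript_id "PB.1.2";
chr1	isoforge	exon	1278	1520	.	+	.	gene_id "GENA"; transcript_id "PB.1.2";
chr1	isoforge	exon	1629	1895	.	+	.	gene_id "GENA"; transcript_id "PB.1.2";
chr1	isoforge	exon	1995	2249	.	+	.	gene_id "GENA"; transcript_id "PB.1.2";
chr1	isoforge	CDS	579	764	.	+	.	gene_id "GENA"; transcript_id "PB.1.2";
chr1	isoforge	CDS	909	1172	.	+	.	gene_id "GENA"; transcript_id "PB.1.2";
chr1	isoforge	CDS	1278	1520	.	+	.	gene_id "GENA"; transcript_id "PB.1.2";
chr1	isoforge	CDS	1629	1895	.	+	.	gene_id "GENA"; transcript_id "PB.1.2";
chr1	isoforge	CDS	1995	2204	.	+	.	gene_id "GENA"; transcript_id "PB.1.2";
chr1	isoforge	exon	201	449	.	+	.	gene_id "GENA"; transcript_id "PB.1.3";
chr1	isoforge	exon	570	764	.	+	.	gene_id "GENA"; transcript_id "PB.1.3";
chr1	isoforge	exon	909	1172	.	+	.	gene_id "GENA"; transcript_id "PB.1.3";
chr1	isoforge	exon	1278	1520	.	+	.	gene_id "GENA"; transcript_id "PB.1.3";
chr1	isoforge	exon	1995	2249	.	+	.	gene_id "GENA"; transcript_id "PB.1.3";
chr1	isoforge	CDS	579	764	.	+	.	gene_id "GENA"; transcript_id "PB.1.3";
chr1	isoforge	CDS	909	1172	.	+	.	gene_id "GENA"; transcript_id "PB.1.3";
chr1	isoforge	CDS	1278	1520	.	+	.	gene_id "GENA"; transcript_id "PB.1.3";
chr1	isoforge	CDS	1995	2204	.	+	.	gene_id "GENA"; transcript_id "PB.1.3";
chr1	isoforge	exon	201	449	.	+	.	gene_id "GENA"; transcript_id "PB.1.4";
chr1	isoforge	exon	570	764	.	+	.	gene_id "GENA"; transcript_id "PB.1.4";
chr1	isoforge	exon	909	1172	.	+	.	gene_id "GENA"; transcript_id "PB.1.4";
chr1	isoforge	exon	1278	1895	.	+	.	gene_id "GENA"; transcript_id "PB.1.4";
chr1	isoforge	exon	1995	2249	.	+	.	gene_id "GENA"; transcript_id "PB.1.4";
chr1	isoforge	CDS	579	764	.	+	.	gene_id "GENA"; transcript_id "PB.1.4";
chr1	isoforge	CDS	909	1172	.	+	.	gene_id "GENA"; transcript_id "PB.1.4";
chr1	isoforge	CDS	1278	1895	.	+	.	gene_id "GENA"; transcript_id "PB.1.4";
chr1	isoforge	CDS	1995	2204	.	+	.	gene_id "GENA"; transcript_id "PB.1.4";
chr2	isoforge	exon	201	432	.	-	.	gene_id "GENB"; transcript_id "PB.2.1";
chr2	isoforge	exon	565	759	.	-	.	gene_id "GENB"; transcript_id "PB.2.1";
chr2	isoforge	exon	853	1107	.	-	.	gene_id "GENB"; transcript_id "PB.2.1";
chr2	isoforge	exon	1222	1410	.	-	.	gene_id "GENB"; transcript_id "PB.2.1";
chr2	isoforge	exon	1531	1735	.	-	.	gene_id "GENB"; transcript_id "PB.2.1";
chr2	isoforge	exon	1859	2097	.	-	.	gene_id "GENB"; transcript_id "PB.2.1";
chr2	isoforge	CDS	244	432	.	-	.	gene_id "GENB"; transcript_id "PB.2.1";
chr2	isoforge	CDS	565	759	.	-	.	gene_id "GENB"; transcript_id "PB.2.1";
chr2	isoforge	CDS	853	1107	.	-	.	gene_id "GENB"; transcript_id "PB.2.1";
chr2	isoforge	CDS	1222	1410	.	-	.	gene_id "GENB"; transcript_id "PB.2.1";
chr2	isoforge	CDS	1531	1719	.	-	.	gene_id "GENB"; transcript_id "PB.2.1";
chr2	isoforge	exon	201	432	.	-	.	gene_id "GENB"; transcript_id "PB.2.2";
chr2	isoforge	exon	565	759	.	-	.	gene_id "GENB"; transcript_id "PB.2.2";
chr2	isoforge	exon	1222	1410	.	-	.	gene_id "GENB"; transcript_id "PB.2.2";
chr2	isoforge	exon	1531	1735	.	-	.	gene_id "GENB"; transcript_id "PB.2.2";
chr2	isoforge	exon	1859	2097	.	-	.	gene_id "GENB"; transcript_id "PB.2.2";
chr2	isoforge	CDS	244	432	.	-	.	gene_id "GENB"; transcript_id "PB.2.2";
chr2	isoforge	CDS	565	759	.	-	.	gene_id "GENB"; transcript_id "PB.2.2";
chr2	isoforge	CDS	1222	1410	.	-	.	gene_id "GENB"; transcript_id "PB.2.2";
chr2	isoforge	CDS	1531	1719	.	-	.	gene_id "GENB"; transcript_id "PB.2.2";
chr2	isoforge	exon	201	432	.	-	.	gene_id "GENB"; transcript_id "PB.2.3";
chr2	isoforge	exon	565	759	.	-	.	gene_id "GENB"; transcript_id "PB.2.3";
chr2	isoforge	exon	1222	1263	.	-	.	gene_id "GENB"; transcript_id "PB.2.3";
chr2	isoforge	CDS	244	432	.	-	.	gene_id "GENB"; transcript_id "PB.2.3";
chr2	isoforge	CDS	565	759	.	-	.	gene_id "GENB"; transcript_id "PB.2.3";
chr2	isoforge	CDS	1222	1263	.	-	.	gene_id "GENB"; transcript_id "PB.2.3";
chr2	isoforge	exon	201	432	.	-	.	gene_id "GENB"; transcript_id "PB.2.4";
chr2	isoforge	exon	565	756	.	-	.	gene_id "GENB"; transcript_id "PB.2.4";
chr2	isoforge	CDS	244	432	.	-	.	gene_id "GENB"; transcript_id "PB.2.4";
chr2	isoforge	CDS	565	747	.	-	.	gene_id "GENB"; transcript_id "PB.2.4";
chr3	isoforge	exon	201	435	.	+	.	gene_id "GENC"; transcript_id "PB.3.1";
chr3	isoforge	exon	544	839	.	+	.	gene_id "GENC"; transcript_id "PB.3.1";
chr3	isoforge	exon	960	1181	.	+	.	gene_id "GENC"; transcript_id "PB.3.1";
chr3	isoforge	exon	1287	1547	.	+	.	gene_id "GENC"; transcript_id "PB.3.1";
chr3	isoforge	exon	1689	1940	.	+	.	gene_id "GENC"; transcript_id "PB.3.1";
chr3	isoforge	exon	2034	2253	.	+	.	gene_id "GENC"; transcript_id "PB.3.1";
chr3	isoforge	CDS	570	839	.	+	.	gene_id "GENC"; transcript_id "PB.3.1";
chr3	isoforge	CDS	960	1181	.	+	.	gene_id "GENC"; transcript_id "PB.3.1";
chr3	isoforge	CDS	1287	1547	.	+	.	gene_id "GENC"; transcript_id "PB.3.1";
chr3	isoforge	CDS	1689	1940	.	+	.	gene_id "GENC"; transcript_id "PB.3.1";
chr3	isoforge	CDS	2034	2216	.	+	.	gene_id "GENC"; transcript_id "PB.3.1";
chr3	isoforge	exon	1113	1181	.	+	.	gene_id "GENC"; transcript_id "PB.3.2";
chr3	isoforge	exon	1287	1547	.	+	.	gene_id "GENC"; transcript_id "PB.3.2";
chr3	isoforge	exon	1689	1940	.	+	.	gene_id "GENC"; transcript_id "PB.3.2";
chr3	isoforge	exon	2034	2253	.	+	.	gene_id "GENC"; transcript_id "PB.3.2";
chr3	isoforge	CDS	1113	1181	.	+	.	gene_id "GENC"; transcript_id "PB.3.2";
chr3	isoforge	CDS	1287	1547	.	+	.	gene_id "GENC"; transcript_id "PB.3.2";
chr3	isoforge	CDS	1689	1940	.	+	.	gene_id "GENC"; transcript_id "PB.3.2";
chr3	isoforge	CDS	2034	2216	.	+	.	gene_id "GENC"; transcript_id "PB.3.2";
chr3	isoforge	exon	201	435	.	+	.	gene_id "GENC"; transcript_id "PB.3.3";
chr3	isoforge	exon	544	839	.	+	.	gene_id "GENC"; transcript_id "PB.3.3";
chr3	isoforge	exon	960	1181	.	+	.	gene_id "GENC"; transcript_id "PB.3.3";
chr3	isoforge	exon	1287	1547	.	+	.	gene_id "GENC"; transcript_id "PB.3.3";
chr3	isoforge	exon	2034	2253	.	+	.	gene_id "GENC"; transcript_id "PB.3.3";
chr3	isoforge	CDS	570	839	.	+	.	gene_id "GENC"; transcript_id "PB.3.3";
chr3	isoforge	CDS	960	1181	.	+	.	gene_id "GENC"; transcript_id "PB.3.3";
chr3	isoforge	CDS	1287	1547	.	+	.	gene_id "GENC"; transcript_id "PB.3.3";
chr3	isoforge	CDS	2034	2216	.	+	.	gene_id "GENC"; transcript_id "PB.3.3";
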