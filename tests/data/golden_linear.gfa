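H	VN:Z:1.0
S	1	TACTATACTCCC
S	2	GCTCCGGGG
S	3	TTTGGCTCAT
S	4	ATGAACAAGTCT
S	5	TTGCGCCCA
S	6	TAAATGTAGC
S	7	CAGTGAGCTTA
S	8	GTTGGA
S	9	GCAA
S	10	GGGGTG
S	11	CGGAAG
S	12	CGCAACTCCGT
L	1	+	2	+	0M
L	2	+	3	+	0M
L	3	+	4	+	0M
L	4	+	5	+	0M
L	5	+	6	+	0M
L	6	+	7	+	0M
L	7	+	8	+	0M
L	8	+	9	+	0M
L	9	+	10	+	0M
L	10	+	11	+	0M
L	11	+	12	+	0M
P	ref	1+,2+,3+,4+,5+,6+,7+,8+,9+,10+,11+,12+	*
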