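sample_id	genotype	allele	cpg_index	methylation_pct
CD4	CT	C	1	77
CD4	CT	T	1	49
CD4	CT	C	2	67
CD4	CT	T	2	42
CD5	CT	C	1	89
CD5	CT	T	1	73
CD5	CT	C	2	86
CD5	CT	T	2	64
UC1	CT	C	1	77
UC1	CT	T	1	77
UC1	CT	C	2	74
UC1	CT	T	2	69
UC4	CT	C	1	87
UC4	CT	T	1	78
UC4	CT	C	2	82
UC4	CT	T	2	74
CD7	CC	C	1	82
CD7	CC	C	2	76
CD6	TT	T	1	60
CD6	TT	T	2	53
CD8	TT	T	1	69
CD8	TT	T	2	66
UC5	TT	T	1	61
UC5	TT	T	2	55
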