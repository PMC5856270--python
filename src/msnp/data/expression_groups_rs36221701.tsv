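gene_name	mean_fpkm_tt	mean_fpkm_ct	mean_fpkm_cc	n_tt	n_ct	n_cc
SMAD6	0.02	0	0	6	4	1
SMAD3	43.91	76.33	120.47	6	4	1
IQCH	0.10	0.07	0	6	4	1
C15orf61	17.97	20.62	18.43	6	4	1
MAP2K5	10.44	8.42	6.71	6	4	1
SKOR1	0.02	0.01	0	6	4	1
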