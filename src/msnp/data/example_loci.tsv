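locus_id	tag_snp	chrom	gene_name	gene_start	gene_end
smad3	rs36221701	15	SMAD3	67357990	67487569
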