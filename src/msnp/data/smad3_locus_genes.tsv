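gene_name	chrom	gene_start	gene_end
SMAD6	15	66994673	67074338
SMAD3	15	67357990	67487569
IQCH	15	67547137	67819641
C15orf61	15	67547137	67819641
MAP2K5	15	67835020	68099455
SKOR1	15	68112041	68126174
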