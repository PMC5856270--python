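"""Scan probe flanks for methylation-sensitive restriction sites.

A probe enters the ASM analysis population only if at least one allele's
flanking sequence carries a site for the HpaII/HhaI/AciI cocktail; a SNP
that makes or breaks a site is flagged because digestion then tracks
genotype, not methylation.
"""

from msnp import (
    ProbeRecord,
    alleles_distinguishable_after_bisulfite,
    bisulfite_convert,
    probe_site_counts,
    scan_msre_sites,
)

seq = "TTCCGGATGCGCTACCGCAA"
print(f"sites in {seq}:")
for hit in scan_msre_sites(seq):
    print(f"  {hit.enzyme_name:6s} offset {hit.offset:2d} strand {hit.strand}")
# HpaII/HhaI are palindromic (one + strand hit each); AciI is scanned on
# both strands, so CCGC and its reverse complement GCGG are both reported.

probe = ProbeRecord("rs_demo", "1", 1000, "C", "T", "AACCGGAA", variant_index=3)
counts = probe_site_counts(probe)
print(f"\nprobe rs_demo site counts per allele (C, T): {counts}")
# (1, 0): the T allele destroys the only HpaII site — a cut-site SNP that
# the cluster QC stage would flag.

print("\nbisulfite conversion of ACGTACGA, CpG at offset 5 methylated:")
print(" ", bisulfite_convert("ACGTACGA", {5}))
# the unmethylated CpG at offset 1 reads T, the methylated one at 5 keeps its C

print("\nC/T alleles distinguishable after conversion?",
      alleles_distinguishable_after_bisulfite("C", "T"))
# False: an unmethylated C converts to T, merging with the native T allele —
# the reason allele-specific PCR falls back to an LD-proxy SNP.
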