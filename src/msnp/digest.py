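"""Methylation-sensitive restriction sites and bisulfite-conversion logic.

A methylation-sensitive restriction enzyme (MSRE) cleaves its recognition
sequence only when the internal CpG is unmethylated.  The analysis population
of a methylation-sensitive SNP array consists of probes whose flanking
sequence carries at least one site for the enzyme cocktail (HpaII, HhaI,
AciI); after digestion the signal of an unmethylated allele collapses while a
methylated allele survives, shifting the relative allele score.

Bisulfite chemistry converts unmethylated cytosine to uracil (read as
thymine) and leaves methylated CpG cytosines intact.  The helpers here model
that conversion on the forward strand and decide whether a SNP's alleles
remain distinguishable after conversion — a C/T SNP does not, which is why
allele-specific PCR designs fall back to an LD-proxy variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Enzyme",
    "SiteHit",
    "ProbeRecord",
    "HPAII",
    "HHAI",
    "ACII",
    "DEFAULT_ENZYMES",
    "reverse_complement",
    "scan_msre_sites",
    "probe_site_counts",
    "in_analysis_population",
    "bisulfite_convert",
    "alleles_distinguishable_after_bisulfite",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA_CHARS = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A methylation-sensitive restriction enzyme.

    Parameters
    ----------
    name : str
        Conventional enzyme name (e.g. ``"HpaII"``).
    recognition : str
        Recognition sequence, 5'→3', plain A/C/G/T (no ambiguity codes).
        Must contain at least one CpG dinucleotide: the enzyme is
        methylation-sensitive precisely because methylation of that CpG
        blocks cleavage.
    cut_offset : int
        0-based position of the cleavage point within the recognition
        sequence (HpaII C^CGG → 1).
    palindromic : bool
        True when the recognition sequence equals its own reverse
        complement, in which case a single scan of the forward strand
        covers both strands.
    """

    name: str
    recognition: str
    cut_offset: int
    palindromic: bool

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition site shorter than 4 bp")
        if not set(self.recognition) <= frozenset("ACGT"):
            raise ValueError(f"{self.name}: recognition must be plain A/C/G/T")
        if "CG" not in self.recognition:
            raise ValueError(
                f"{self.name}: no CpG in recognition site — not methylation-sensitive"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut_offset outside recognition site")

    @property
    def cpg_offset(self) -> int:
        """Offset of the first CpG within the recognition sequence."""
        return self.recognition.index("CG")


HPAII = Enzyme("HpaII", "CCGG", 1, palindromic=True)
HHAI = Enzyme("HhaI", "GCGC", 3, palindromic=True)
ACII = Enzyme("AciI", "CCGC", 1, palindromic=False)

#: The three-enzyme cocktail used throughout the pipeline.
DEFAULT_ENZYMES: tuple[Enzyme, ...] = (HPAII, HHAI, ACII)


@dataclass(frozen=True)
class SiteHit:
    """One occurrence of an enzyme recognition site on a sequence.

    ``offset`` is the 0-based start of the site on the *given* (forward)
    sequence; ``strand`` is ``"-"`` when the site was found as the reverse
    complement of a non-palindromic recognition sequence.
    """

    enzyme_name: str
    offset: int
    strand: str  # "+" or "-"


@dataclass
class ProbeRecord:
    """One array SNP probe: location, alleles and flanking context.

    ``flank`` holds the probe's genomic context with the variant base at
    ``variant_index`` (whatever base happens to be written there is replaced
    when counting sites per allele).  ``pos`` is 1-based.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    flank: str
    variant_index: int
    msre_sites_a: int = field(default=-1)
    msre_sites_b: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if not 0 <= self.variant_index < len(self.flank):
            raise ValueError(f"{self.snp_id}: variant_index outside flank")


def _validate_dna(seq: str) -> None:
    bad = set(seq) - _DNA_CHARS
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)!r}")


def _find_all(seq: str, pattern: str) -> list[int]:
    # str.find with a moving start catches overlapping occurrences
    hits = []
    i = seq.find(pattern)
    while i != -1:
        hits.append(i)
        i = seq.find(pattern, i + 1)
    return hits


def scan_msre_sites(
    seq: str, enzymes: tuple[Enzyme, ...] | list[Enzyme] = DEFAULT_ENZYMES
) -> list[SiteHit]:
    """Find every MSRE recognition site on a double-stranded sequence.

    Palindromic enzymes are reported once, on the + strand.  Non-palindromic
    enzymes (AciI) are additionally scanned as their reverse complement and
    reported as − strand hits, since duplex DNA is cut when either strand
    presents the site.  ``N`` bases never complete a site.

    Returns hits sorted by offset (ties broken by enzyme name, then strand).
    """
    if not enzymes:
        raise ValueError("enzymes must be non-empty")
    _validate_dna(seq)
    hits: list[SiteHit] = []
    for enz in enzymes:
        for off in _find_all(seq, enz.recognition):
            hits.append(SiteHit(enz.name, off, "+"))
        if not enz.palindromic:
            rc = reverse_complement(enz.recognition)
            for off in _find_all(seq, rc):
                hits.append(SiteHit(enz.name, off, "-"))
    hits.sort(key=lambda h: (h.offset, h.enzyme_name, h.strand))
    return hits


def probe_site_counts(
    probe: ProbeRecord,
    enzymes: tuple[Enzyme, ...] | list[Enzyme] = DEFAULT_ENZYMES,
) -> tuple[int, int]:
    """Count intact MSRE sites in the probe flank under each allele.

    The variant base is substituted with allele A and allele B in turn and
    the flank rescanned; an allele that creates or destroys a recognition
    site yields asymmetric counts (such probes confound digestion signal
    with genotype and are flagged downstream).
    """
    flank = probe.flank.upper()
    i = probe.variant_index
    seq_a = flank[:i] + probe.allele_a.upper() + flank[i + 1 :]
    seq_b = flank[:i] + probe.allele_b.upper() + flank[i + 1 :]
    return len(scan_msre_sites(seq_a, enzymes)), len(scan_msre_sites(seq_b, enzymes))


def in_analysis_population(count_a: int, count_b: int) -> bool:
    """A probe is analyzable iff at least one allele carries ≥1 MSRE site."""
    return max(count_a, count_b) >= 1


def bisulfite_convert(seq: str, methylated_cpg_offsets: set[int] | frozenset[int]) -> str:
    """Bisulfite-convert a forward-strand sequence.

    Every cytosine outside a methylated CpG becomes thymine (C → U → T
    through PCR); cytosines of CpGs listed in ``methylated_cpg_offsets``
    are protected.  Offsets must point at the C of a CpG dinucleotide.
    """
    _validate_dna(seq)
    for off in methylated_cpg_offsets:
        if not (0 <= off < len(seq) - 1 and seq[off] == "C" and seq[off + 1] == "G"):
            raise ValueError(f"offset {off} is not the C of a CpG in the sequence")
    out = []
    for i, base in enumerate(seq):
        if base == "C" and i not in methylated_cpg_offsets:
            out.append("T")
        else:
            out.append(base)
    return "".join(out)


def alleles_distinguishable_after_bisulfite(allele_1: str, allele_2: str) -> bool:
    """Whether two SNP alleles remain readable after bisulfite conversion.

    On the sequenced (forward) strand an unmethylated C allele converts to
    T, so a C/T SNP collapses to T/T and the allele of origin is lost —
    the situation that forces an allele-specific PCR design onto an LD-proxy
    SNP.  Every other allele pair stays distinguishable.
    """
    a1, a2 = allele_1.upper(), allele_2.upper()
    if a1 == a2:
        raise ValueError("alleles must differ")
    return {a1, a2} != {"C", "T"}
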