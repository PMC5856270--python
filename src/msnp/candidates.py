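"""Candidate extraction funnel for cis-regulated allele-specific methylation.

The funnel mirrors the selection flowchart of a methylation-sensitive SNP
array study: start from all probes, keep the analysis population (≥1 MSRE
site on either allele), drop probes failing the two exclusion criteria,
require ΔRAS̄ above threshold, restrict to windows around susceptibility
genes, and finally apply quantitative quality control in place of manual
cluster-plot inspection.  Each stage only removes probes, so per-stage
counts decrease monotonically.

Direction classification separates cis-ASM (the methylated allele is fixed
by genotype — RAS shifts one way in every heterozygote) from imprinting
(methylation follows parental origin — shifts go both ways).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SusceptibilityLocus",
    "ASMCandidate",
    "CandidateConfig",
    "select_heterozygotes",
    "classify_direction",
    "within_window",
    "cluster_qc",
    "extract_candidates",
]


@dataclass(frozen=True)
class SusceptibilityLocus:
    """A susceptibility gene interval with its GWAS tag-SNP.

    Coordinates are 1-based inclusive.  A zero-width interval
    (gene_start == gene_end at the tag-SNP position) evaluates the tag-SNP
    itself rather than a gene body.
    """

    locus_id: str
    tag_snp: str
    chrom: str
    gene_name: str
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.gene_start > self.gene_end:
            raise ValueError(f"{self.locus_id}: gene_start > gene_end")


@dataclass
class ASMCandidate:
    snp_id: str
    delta_ras_bar: float
    signed_delta: float
    n_het: int
    direction: str  # monoallelic / biallelic / indeterminate
    matched_genes: list[tuple[str, int]] = field(default_factory=list)
    qc_flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CandidateConfig:
    """Thresholds of the candidate stage (defaults follow the study design)."""

    window_bp: int = 100_000
    concordance_frac: float = 0.9
    min_shift: float = 0.05
    u_shift_max: float = 0.1
    cv_max: float = 1.0
    min_het_candidate: int = 4


def select_heterozygotes(genotypes: pd.DataFrame, snp_id: str) -> list[str]:
    """Sample ids called AB at ``snp_id`` on the genomic (G) arrays, in
    input order.  NoCall samples are never selected."""
    sub = genotypes[(genotypes["snp_id"] == snp_id) & (genotypes["call"] == "AB")]
    return list(sub["sample_id"])

def classify_direction(
    shifts: list[float],
    concordance_frac: float = 0.9,
    min_shift: float = 0.05,
) -> str:
    """Classify per-heterozygote RAS shifts as monoallelic or biallelic.

    Only *qualifying* shifts (|shift| ≥ min_shift) carry direction
    information.  ``monoallelic``: at least ``concordance_frac`` of
    qualifying shifts share one sign — the cis-ASM signature.
    ``biallelic``: each sign holds at least ``1 − concordance_frac`` of
    qualifying shifts — the imprinting signature.  Anything else (including
    fewer than two qualifying shifts) is ``indeterminate``.
    """
    if len(shifts) < 2:
        return "indeterminate"
    qual = [s for s in shifts if abs(s) >= min_shift]
    if len(qual) < 2:
        return "indeterminate"
    frac_pos = sum(s > 0 for s in qual) / len(qual)
    if max(frac_pos, 1 - frac_pos) >= concordance_frac:
        return "monoallelic"
    if min(frac_pos, 1 - frac_pos) >= 1 - concordance_frac:
        return "biallelic"
    return "indeterminate"


def within_window(
    snp: tuple[str, int], locus: SusceptibilityLocus, window_bp: int = 100_000
) -> bool:
    """True iff the SNP lies within ``window_bp`` of the locus interval
    (same chromosome; boundaries inclusive)."""
    chrom, pos = snp
    if chrom != locus.chrom:
        return False
    return locus.gene_start - window_bp <= pos <= locus.gene_end + window_bp


def _gene_distance(pos: int, locus: SusceptibilityLocus) -> int:
    if pos < locus.gene_start:
        return locus.gene_start - pos
    if pos > locus.gene_end:
        return pos - locus.gene_end
    return 0


def cluster_qc(
    het_shift_u: float,
    cv_g_distance: float,
    n_het: int,
    config: CandidateConfig = CandidateConfig(),
) -> list[str]:
    """Quantitative surrogate for manual signal-cluster inspection.

    Flags raised:

    * ``cut-site-artifact`` — heterozygote RAS in the fully unmethylated
      control (U) is shifted from RAS_G by more than ``u_shift_max``: the
      SNP itself creates/destroys a cut site, so digestion signal tracks
      genotype rather than methylation.
    * ``unstable-hybridization`` — coefficient of variation of the
      per-sample G-condition signal distance exceeds ``cv_max``.
    * ``insufficient-heterozygotes`` — fewer than ``min_het_candidate``
      informative heterozygotes.
    """
    flags = []
    if np.isfinite(het_shift_u) and abs(het_shift_u) > config.u_shift_max:
        flags.append("cut-site-artifact")
    if cv_g_distance > config.cv_max:
        flags.append("unstable-hybridization")
    if n_het < config.min_het_candidate:
        flags.append("insufficient-heterozygotes")
    return flags


def extract_candidates(
    stats: pd.DataFrame,
    het_shifts: pd.DataFrame,
    site_counts: pd.DataFrame,
    probe_positions: pd.DataFrame,
    loci: list[SusceptibilityLocus],
    config: CandidateConfig = CandidateConfig(),
    delta_ras_threshold: float = 0.1,
) -> tuple[list[ASMCandidate], dict[str, int]]:
    """Run the selection funnel and return candidates plus per-stage counts.

    Parameters
    ----------
    stats, het_shifts : per-probe statistics from :func:`msnp.ras.compute_probe_stats`
    site_counts : DataFrame with snp_id, msre_sites_a, msre_sites_b
    probe_positions : DataFrame with snp_id, chrom, pos (1-based)
    loci : susceptibility loci; must be non-empty
    config : thresholds for window, direction and QC
    delta_ras_threshold : ΔRAS̄ cut for calling ASM

    Returns
    -------
    candidates : list of :class:`ASMCandidate`, sorted by ΔRAS̄ descending.
        Candidates passing QC are reported regardless of direction class
        (an imprinted probe appears with direction ``biallelic``).
    funnel : ordered stage → surviving probe count
    """
    if not loci:
        raise ValueError("loci table is empty — cannot window candidates")

    funnel: dict[str, int] = {}
    funnel["input_probes"] = len(site_counts)

    sc = site_counts.set_index("snp_id")
    pop = sc[(sc[["msre_sites_a", "msre_sites_b"]].max(axis=1)) >= 1]
    funnel["analysis_population"] = len(pop)

    st = stats[stats["snp_id"].isin(pop.index)]
    kept = st[st["excluded_by"] == "none"]
    funnel["passed_exclusion"] = len(kept)

    asm = kept[kept["evaluable"] & (kept["delta_ras_bar"] > delta_ras_threshold)]
    funnel["delta_ras_above_threshold"] = len(asm)

    pos = probe_positions.set_index("snp_id")
    in_window: dict[str, list[tuple[str, int]]] = {}
    for snp_id in asm["snp_id"]:
        p = pos.loc[snp_id]
        matches = [
            (loc.gene_name, _gene_distance(int(p["pos"]), loc))
            for loc in loci
            if within_window((str(p["chrom"]), int(p["pos"])), loc, config.window_bp)
        ]
        if matches:
            in_window[snp_id] = sorted(matches, key=lambda m: m[1])
    windowed = asm[asm["snp_id"].isin(in_window)]
    funnel["in_susceptibility_window"] = len(windowed)

    shifts_by_snp = het_shifts.groupby("snp_id")["shift"].agg(list)
    candidates: list[ASMCandidate] = []
    for _, row in windowed.iterrows():
        snp_id = row["snp_id"]
        flags = cluster_qc(
            row["het_shift_u"], row["cv_g_distance"], int(row["n_het"]), config
        )
        if flags:
            continue
        direction = classify_direction(
            shifts_by_snp.get(snp_id, []),
            config.concordance_frac,
            config.min_shift,
        )
        candidates.append(
            ASMCandidate(
                snp_id=snp_id,
                delta_ras_bar=float(row["delta_ras_bar"]),
                signed_delta=float(row["signed_delta"]),
                n_het=int(row["n_het"]),
                direction=direction,
                matched_genes=in_window[snp_id],
                qc_flags=[],
            )
        )
    funnel["passed_qc"] = len(candidates)
    candidates.sort(key=lambda c: -c.delta_ras_bar)
    return candidates, funnel
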