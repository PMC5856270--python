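"""Allele-specific bisulfite-pyrosequencing statistics.

After allele-specific PCR, the two allelic amplicons of a heterozygote are
pyrosequenced separately, yielding a per-allele methylation percentage for
each CpG in the assay.  This module summarizes those measurements and runs
the two comparisons used to validate array-detected ASM:

* a paired t-test on the per-heterozygote (C − T) allele differences — the
  within-individual design that cancels environmental methylation variation;
* an exact Mann–Whitney (Wilcoxon rank-sum) test when homozygotes' single
  alleles are pooled in, making the groups unpaired and unequal in size.

Input is a long-format table: sample_id, genotype, allele, cpg_index,
methylation_pct.  A packaged fixture carries the published measurements
around rs36221701 (four C/T heterozygotes, one C/C and three T/T
homozygotes, two CpGs).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "AlleleSummary",
    "per_allele_summary",
    "paired_allele_test",
    "combined_rank_test",
    "exact_rank_sum_test",
    "allele_specific_pcr_pass",
]


@dataclass(frozen=True)
class AlleleSummary:
    mean_c: float
    sd_c: float
    n_c: int
    mean_t: float
    sd_t: float
    n_t: int


def _is_het(genotype: str) -> bool:
    return len(set(genotype)) == 2


def per_allele_summary(
    measurements: pd.DataFrame, cpg_index: int, population: str = "het_only"
) -> AlleleSummary:
    """Mean/SD/n of methylation per allele at one CpG.

    ``population="het_only"`` uses heterozygous samples (both alleles
    measured within each individual); ``"all"`` additionally pools the
    single allele each homozygote carries.  SDs use the n−1 denominator.
    """
    if population not in ("het_only", "all"):
        raise ValueError(f"unknown population {population!r}")
    sub = measurements[measurements["cpg_index"] == cpg_index]
    if population == "het_only":
        sub = sub[sub["genotype"].map(_is_het)]
    out = {}
    for allele in ("C", "T"):
        vals = sub.loc[sub["allele"] == allele, "methylation_pct"].to_numpy(float)
        if len(vals) == 0:
            raise ValueError(f"no measurements for allele {allele}")
        out[allele] = (
            float(vals.mean()),
            float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            len(vals),
        )
    return AlleleSummary(*out["C"], *out["T"])


def paired_allele_test(
    measurements: pd.DataFrame, cpg_index: int
) -> tuple[float, int, float]:
    """Paired t-test of C vs T allele methylation in heterozygotes.

    Returns (t, df, two-sided p) on the per-sample differences C − T.
    With zero variance of differences the p-value is degenerate: 1.0 when
    every difference is zero, 0.0 otherwise (warned).
    """
    sub = measurements[
        (measurements["cpg_index"] == cpg_index)
        & measurements["genotype"].map(_is_het)
    ]
    wide = sub.pivot(index="sample_id", columns="allele", values="methylation_pct")
    wide = wide.dropna(subset=["C", "T"])
    if len(wide) < 2:
        raise ValueError("need ≥2 heterozygotes with both alleles measured")
    d = (wide["C"] - wide["T"]).to_numpy(float)
    n = len(d)
    if d.std(ddof=1) == 0:
        warnings.warn("zero variance of paired differences; p degenerate")
        t = 0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean())
        return t, n - 1, 1.0 if d.mean() == 0 else 0.0
    res = stats.ttest_rel(wide["C"], wide["T"])
    return float(res.statistic), n - 1, float(res.pvalue)


def exact_rank_sum_test(
    group1: np.ndarray, group2: np.ndarray, max_enumeration: int = 2_000_000
) -> tuple[float, float]:
    """Exact two-sided Wilcoxon rank-sum (Mann–Whitney) test with midranks.

    The null distribution of the group-1 rank sum is obtained by
    enumerating every assignment of the pooled midranks to a group of size
    n1; ties are handled naturally because midranks are enumerated, not
    integer ranks.  The two-sided p-value is the probability of a rank sum
    at least as far from its null mean as observed.  Returns
    (U statistic of group 1, p).  Falls back to the normal approximation
    with tie correction when the enumeration count exceeds
    ``max_enumeration``.
    """
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    n1, n2 = len(g1), len(g2)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    ranks = stats.rankdata(pooled)
    r_obs = ranks[:n1].sum()
    u_obs = r_obs - n1 * (n1 + 1) / 2
    mu = n1 * (n1 + n2 + 1) / 2
    dev = abs(r_obs - mu)

    n_comb = special.comb(n1 + n2, n1, exact=True)
    if n_comb <= max_enumeration:
        eps = 1e-9
        count = sum(
            1
            for idx in combinations(range(n1 + n2), n1)
            if abs(ranks[list(idx)].sum() - mu) >= dev - eps
        )
        return float(u_obs), count / n_comb
    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12 * (n + 1 - tie_term)
    if var == 0:
        return float(u_obs), 1.0
    z = (dev - 0.5) / math.sqrt(var)
    return float(u_obs), float(2 * stats.norm.sf(z))


def combined_rank_test(
    measurements: pd.DataFrame, cpg_index: int
) -> tuple[float, float]:
    """Compare C vs T allele methylation pooling heterozygotes and
    homozygotes at one CpG.

    With homozygotes included the two allele groups are unpaired and of
    unequal size, so the comparison is an exact Mann–Whitney rank-sum test
    (midranks for ties).  Returns (U statistic of the C group, two-sided p);
    completely tied groups give p = 1.
    """
    sub = measurements[measurements["cpg_index"] == cpg_index]
    c = sub.loc[sub["allele"] == "C", "methylation_pct"].to_numpy(float)
    t = sub.loc[sub["allele"] == "T", "methylation_pct"].to_numpy(float)
    if len(c) == 0 or len(t) == 0:
        raise ValueError("both allele groups must be non-empty")
    return exact_rank_sum_test(c, t)


def allele_specific_pcr_pass(specificity_pct: float, threshold: float = 85.0) -> bool:
    """Whether an allele-specific PCR is specific enough to trust the
    allelic amplicon (fraction of reads carrying the targeted allele at the
    control SNP)."""
    if not 0 <= specificity_pct <= 100:
        raise ValueError("specificity must be a percentage in [0, 100]")
    return specificity_pct >= threshold
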