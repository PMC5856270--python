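"""Relative allele score (RAS) statistics for methylation-sensitive SNP arrays.

Each probe is assayed under three conditions per individual:

* **G** — undigested genomic DNA (genotype reference),
* **D** — genomic DNA digested with the MSRE cocktail,
* **U** — whole-genome-amplified (hence fully unmethylated) DNA, digested;
  the control for cutting efficiency and for SNPs at cut sites.

RAS = A/(A+B) measures the fraction of probe signal attributable to allele
A, analogous to a B-allele frequency.  In a heterozygote, allele-specific
methylation (ASM) protects one allele from digestion, so RAS moves between
the G and D arrays.  The per-probe ASM score ΔRAS̄ is the mean over
heterozygous individuals of |RAS_D − RAS_G|; the signed mean is retained
separately to distinguish cis-ASM (one direction) from imprinting (both).

Two exclusion criteria, both ratios of Euclidean norms of mean (A, B)
intensity pairs against a 1.2 threshold, remove probes that were not cut
informatively (G/U < 1.2) or were unmethylated on both alleles (D/U < 1.2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CONDITIONS",
    "RasConfig",
    "DeltaRasResult",
    "compute_ras",
    "condition_means",
    "distance",
    "exclusion_ratios",
    "apply_exclusion_criteria",
    "delta_ras_bar",
    "compute_probe_stats",
]

CONDITIONS = ("G", "D", "U")


@dataclass(frozen=True)
class RasConfig:
    """Thresholds of the RAS stage.

    ``exclusion_ratio``: minimum distance ratio (G/U and D/U) for a probe to
    be informative; ``delta_ras``: ΔRAS̄ threshold above which a probe is
    called ASM; ``min_het``: minimum heterozygous G/D pairs for a probe to
    be evaluable at all.
    """

    exclusion_ratio: float = 1.2
    delta_ras: float = 0.1
    min_het: int = 2
    #: optional between-array normalization; RAS and the distance ratios
    #: are scale-free within an array, so this is off by default
    median_scale: bool = False


def compute_ras(intensity_a: float, intensity_b: float) -> float:
    """RAS = A / (A + B) for one probe channel pair; in [0, 1]."""
    if intensity_a < 0 or intensity_b < 0:
        raise ValueError("intensities must be non-negative")
    total = intensity_a + intensity_b
    if total == 0:
        raise ValueError("RAS undefined: A + B = 0")
    return intensity_a / total


def condition_means(records: pd.DataFrame) -> tuple[float, float]:
    """Mean (Ā, B̄) over all samples assayed in one condition for one probe.

    ``records`` needs columns ``intensity_a`` / ``intensity_b``.  All
    samples contribute regardless of genotype: the exclusion criteria
    concern cutting and hybridization physics, not allele state.
    """
    if len(records) == 0:
        raise ValueError("no records for condition mean")
    return float(records["intensity_a"].mean()), float(records["intensity_b"].mean())


def distance(mean_pair: tuple[float, float]) -> float:
    """Euclidean norm of a mean (Ā, B̄) pair from the origin."""
    return math.hypot(mean_pair[0], mean_pair[1])


def exclusion_ratios(
    mean_g: tuple[float, float],
    mean_d: tuple[float, float],
    mean_u: tuple[float, float],
) -> tuple[float, float]:
    """distance(Ḡ)/distance(Ū) and distance(D̄)/distance(Ū)."""
    d_u = distance(mean_u)
    if d_u == 0:
        raise ValueError("distance(U) = 0: probe not evaluable")
    return distance(mean_g) / d_u, distance(mean_d) / d_u


def apply_exclusion_criteria(
    ratio_g_u: float, ratio_d_u: float, threshold: float = 1.2
) -> str:
    """Classify a probe against the two exclusion criteria.

    ``criterion1``: G/U below threshold — digestion of the unmethylated
    control did not reduce signal relative to genomic DNA, so the probe is
    not informatively cut (or cross-hybridizes).  ``criterion2``: D/U below
    threshold — digested DNA lost as much signal as the fully unmethylated
    control, i.e. both alleles are unmethylated.  Otherwise ``keep``.
    """
    if not (math.isfinite(ratio_g_u) and math.isfinite(ratio_d_u)):
        raise ValueError("exclusion ratios must be finite")
    if ratio_g_u < threshold:
        return "criterion1"
    if ratio_d_u < threshold:
        return "criterion2"
    return "keep"


@dataclass(frozen=True)
class DeltaRasResult:
    delta_ras_bar: float
    signed_delta: float
    n_het: int
    evaluable: bool
    is_asm: bool


def delta_ras_bar(
    het_pairs: list[tuple[float, float]],
    min_het: int = 2,
    threshold: float = 0.1,
) -> DeltaRasResult:
    """ΔRAS̄ over heterozygotes from per-individual (RAS_G, RAS_D) pairs.

    ``delta_ras_bar`` is the mean absolute RAS change, robust to mixtures of
    directions; ``signed_delta`` is the plain mean change, whose magnitude
    approaches ΔRAS̄ only when all heterozygotes shift the same way.  Below
    ``min_het`` valid pairs the probe is *not evaluable* — reported
    distinctly from an evaluable negative.
    """
    n = len(het_pairs)
    if n < min_het:
        return DeltaRasResult(float("nan"), float("nan"), n, False, False)
    diffs = np.array([d - g for g, d in het_pairs], dtype=float)
    dbar = float(np.mean(np.abs(diffs)))
    sbar = float(np.mean(diffs))
    return DeltaRasResult(dbar, sbar, n, True, dbar > threshold)


def median_scale_arrays(intensities: pd.DataFrame) -> pd.DataFrame:
    """Scale each array (one sample × condition) so its median total
    intensity matches the global median across arrays."""
    out = intensities.copy()
    total = out["intensity_a"] + out["intensity_b"]
    med = total.groupby([out["sample_id"], out["condition"]]).transform("median")
    target = float(
        total.groupby([out["sample_id"], out["condition"]]).median().median()
    )
    factor = np.where(med > 0, target / med, 1.0)
    out["intensity_a"] = out["intensity_a"] * factor
    out["intensity_b"] = out["intensity_b"] * factor
    return out


def _ras_series(sub: pd.DataFrame) -> pd.Series:
    """Per-row RAS with zero-total rows dropped (logged)."""
    total = sub["intensity_a"] + sub["intensity_b"]
    bad = total == 0
    if bad.any():
        logger.warning(
            "dropping %d record(s) with zero total intensity", int(bad.sum())
        )
    sub = sub[~bad]
    return sub["intensity_a"] / (sub["intensity_a"] + sub["intensity_b"])


def compute_probe_stats(
    intensities: pd.DataFrame,
    genotypes: pd.DataFrame,
    config: RasConfig = RasConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-probe RAS statistics over an intensity table.

    Parameters
    ----------
    intensities : DataFrame
        Long format: sample_id, condition (G/D/U), snp_id, intensity_a,
        intensity_b.
    genotypes : DataFrame
        sample_id, snp_id, call ∈ {AA, AB, BB, NoCall} — calls from the G
        (undigested) arrays; heterozygotes are selected from these.
    config : RasConfig

    Returns
    -------
    stats : DataFrame, one row per probe
        Columns: snp_id, n_het, mean intensity pairs per condition
        (a_g…b_u), ratio_g_u, ratio_d_u, excluded_by, delta_ras_bar,
        signed_delta, evaluable, is_asm, het_shift_u (mean RAS_U − RAS_G
        over heterozygotes; cut-site artifact indicator), cv_g_distance
        (coefficient of variation of per-sample G distance).
    het_shifts : DataFrame, one row per (probe, heterozygote)
        snp_id, sample_id, ras_g, ras_d, ras_u, shift (= ras_d − ras_g).
    """
    if config.median_scale:
        intensities = median_scale_arrays(intensities)
    het_by_snp = (
        genotypes[genotypes["call"] == "AB"].groupby("snp_id")["sample_id"].agg(list)
    )
    rows = []
    shift_rows = []
    for snp_id, grp in intensities.groupby("snp_id", sort=True):
        by_cond = {c: grp[grp["condition"] == c] for c in CONDITIONS}
        row: dict = {"snp_id": snp_id}
        if any(len(by_cond[c]) == 0 for c in CONDITIONS):
            logger.warning("%s: missing condition, probe not evaluable", snp_id)
            continue
        means = {c: condition_means(by_cond[c]) for c in CONDITIONS}
        for c in CONDITIONS:
            row[f"a_{c.lower()}"], row[f"b_{c.lower()}"] = means[c]
        try:
            rg, rd = exclusion_ratios(means["G"], means["D"], means["U"])
        except ValueError:
            logger.warning("%s: distance(U)=0, probe not evaluable", snp_id)
            continue
        row["ratio_g_u"], row["ratio_d_u"] = rg, rd
        row["excluded_by"] = (
            "none"
            if apply_exclusion_criteria(rg, rd, config.exclusion_ratio) == "keep"
            else apply_exclusion_criteria(rg, rd, config.exclusion_ratio)
        )

        g_dist = np.hypot(by_cond["G"]["intensity_a"], by_cond["G"]["intensity_b"])
        row["cv_g_distance"] = (
            float(g_dist.std(ddof=1) / g_dist.mean()) if len(g_dist) > 1 else 0.0
        )

        hets = het_by_snp.get(snp_id, [])
        ras = {
            c: _ras_series(by_cond[c].set_index("sample_id")) for c in CONDITIONS
        }
        pairs = []
        u_shifts = []
        for s in hets:
            if s in ras["G"].index and s in ras["D"].index:
                rg_s, rd_s = float(ras["G"][s]), float(ras["D"][s])
                pairs.append((rg_s, rd_s))
                ru_s = float(ras["U"][s]) if s in ras["U"].index else float("nan")
                if not math.isnan(ru_s):
                    u_shifts.append(ru_s - rg_s)
                shift_rows.append(
                    {
                        "snp_id": snp_id,
                        "sample_id": s,
                        "ras_g": rg_s,
                        "ras_d": rd_s,
                        "ras_u": ru_s,
                        "shift": rd_s - rg_s,
                    }
                )
        res = delta_ras_bar(pairs, config.min_het, config.delta_ras)
        row["n_het"] = res.n_het
        row["delta_ras_bar"] = res.delta_ras_bar
        row["signed_delta"] = res.signed_delta
        row["evaluable"] = res.evaluable
        row["is_asm"] = res.is_asm
        row["het_shift_u"] = float(np.mean(u_shifts)) if u_shifts else float("nan")
        rows.append(row)

    stats = pd.DataFrame(rows)
    het_shifts = pd.DataFrame(
        shift_rows, columns=["snp_id", "sample_id", "ras_g", "ras_d", "ras_u", "shift"]
    )
    return stats, het_shifts
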