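"""Generative models for every pipeline input, with truth tables.

The array simulator emulates the three-condition design of a
methylation-sensitive SNP array experiment.  Each probe carries a baseline
hybridization intensity I0 (log-normal across probes); for an allele with
copy number c and k MSRE sites per copy,

* G (genomic):          signal = c · I0 · noise
* D (digested):         signal = I0 · Σ_copies s(copy)^k · noise,
  where the per-site survival s = m + (1 − m) · residual_uncut for copy
  methylation m — a methylated site is refractory to cleavage, an
  unmethylated one survives only at the residual (incomplete-digestion)
  rate,
* U (whole-genome-amplified control, fully unmethylated, then digested):
  signal = c · I0_U · residual_uncut^k · noise, with I0_U an independent
  multiplicative perturbation of I0 (the control derives from a different
  DNA source).

Multiplicative log-normal noise decomposes into a component shared by the
two allele channels of a probe on one array (hybridization efficiency;
cancels in RAS) and a smaller independent per-channel component;
``noise_cv`` is the total coefficient of variation and
``channel_noise_frac`` the variance fraction that is channel-independent.
An additive background floor is applied to every channel.

Truth classes:

* ``null`` — both alleles methylated; survives digestion, RAS unchanged.
* ``cis_asm`` — one genotype-determined allele methylated high, the other
  low; RAS shifts the same way in every heterozygote.
* ``imprinted`` — one randomly chosen chromosome copy per individual
  methylated (parental origin); heterozygote RAS shifts in a random
  direction.
* ``unmethylated`` — no methylation; D collapses like U (exclusion
  criterion 2 territory).
* ``no_site`` — no MSRE site on either allele; all three conditions agree
  (exclusion criterion 1 territory).

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .candidates import SusceptibilityLocus

__all__ = [
    "SimulationConfig",
    "Panel",
    "simulate_panel",
    "simulate_intensities",
    "simulate_pyro",
    "simulate_expression",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic array panel.

    Defaults emulate the source study's scale: 15 individuals, common
    variants (heterozygote frequency ≈ 0.45, matching MAF ≈ 0.35), strong
    allelic methylation contrast (0.9 vs 0.1), 5% residual escape from
    digestion at unmethylated sites, and ~20% total intensity noise of
    which a quarter (in variance) is channel-independent.
    """

    n_probes: int = 1000
    n_samples: int = 15
    het_freq: float = 0.45
    asm_fraction: float = 0.05
    imprint_fraction: float = 0.05
    unmethylated_fraction: float = 0.10
    no_site_fraction: float = 0.10
    methylation_high: float = 0.9
    methylation_low: float = 0.1
    residual_uncut: float = 0.05
    baseline_log_mean: float = math.log(2000.0)
    baseline_log_sd: float = 0.5
    u_baseline_log_sd: float = 0.05
    noise_cv: float = 0.2
    channel_noise_frac: float = 0.25
    background: float = 50.0
    site_count_choices: tuple[int, ...] = (1, 2, 3)
    flank_len: int = 35
    asm_in_window_frac: float = 0.6
    n_loci: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (
            self.asm_fraction
            + self.imprint_fraction
            + self.unmethylated_fraction
            + self.no_site_fraction
        )
        if fr > 1:
            raise ValueError("class fractions sum to more than 1")
        for name in (
            "het_freq",
            "methylation_high",
            "methylation_low",
            "residual_uncut",
            "channel_noise_frac",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.methylation_high <= self.methylation_low:
            raise ValueError("methylation_high must exceed methylation_low")


class Panel(NamedTuple):
    probes: pd.DataFrame  # snp_id, chrom, pos, allele_a, allele_b, flank, variant_index
    loci: list[SusceptibilityLocus]
    truth: pd.DataFrame  # snp_id, class, methylated_allele, sites_a, sites_b
    genotypes: pd.DataFrame  # sample_id, snp_id, call


_GENE_SPACING = 2_000_000
_GENE_LEN = 20_000
_WINDOW = 100_000


def _make_loci(n_loci: int) -> list[SusceptibilityLocus]:
    loci = []
    for g in range(n_loci):
        start = 1_000_000 + g * _GENE_SPACING
        loci.append(
            SusceptibilityLocus(
                locus_id=f"locus{g}",
                tag_snp=f"tag{g}",
                chrom="chr1",
                gene_name=f"GENE{g}",
                gene_start=start,
                gene_end=start + _GENE_LEN - 1,
            )
        )
    return loci


def _make_flank(rng: np.random.Generator, flank_len: int, n_sites: int) -> tuple[str, int]:
    """Flank of A/T background with ``n_sites`` HpaII sites left of the
    variant.  An A/T context guarantees the variant base itself can never
    complete a recognition site, so both alleles carry exactly n_sites."""
    length = 2 * flank_len + 1
    seq = list(rng.choice(["A", "T"], size=length))
    for i in range(n_sites):
        off = 1 + i * 8  # non-overlapping, clear of the centre variant
        seq[off : off + 4] = "CCGG"
    return "".join(seq), flank_len


def simulate_panel(config: SimulationConfig) -> Panel:
    """Draw probes, loci, truth classes and genotype calls.

    cis-ASM and imprinted probes are planted inside a susceptibility-gene
    window with probability ``asm_in_window_frac`` (the rest land in gene
    deserts); other probes are placed uniformly along the chromosome.
    """
    rng = np.random.default_rng(config.seed)
    loci = _make_loci(config.n_loci)
    chrom_len = config.n_loci * _GENE_SPACING + _GENE_SPACING

    classes = rng.choice(
        ["no_site", "unmethylated", "imprinted", "cis_asm", "null"],
        size=config.n_probes,
        p=[
            config.no_site_fraction,
            config.unmethylated_fraction,
            config.imprint_fraction,
            config.asm_fraction,
            1
            - config.no_site_fraction
            - config.unmethylated_fraction
            - config.imprint_fraction
            - config.asm_fraction,
        ],
    )

    probe_rows, truth_rows, geno_rows = [], [], []
    samples = [f"S{i:02d}" for i in range(1, config.n_samples + 1)]
    width = len(str(config.n_probes))
    for i, cls in enumerate(classes):
        snp_id = f"snp{i:0{width}d}"
        if cls in ("cis_asm", "imprinted") and rng.random() < config.asm_in_window_frac:
            loc = loci[rng.integers(len(loci))]
            pos = int(rng.integers(loc.gene_start - _WINDOW, loc.gene_end + _WINDOW + 1))
        elif cls in ("cis_asm", "imprinted"):
            g = rng.integers(config.n_loci)
            lo = 1_000_000 + g * _GENE_SPACING + _GENE_LEN + 3 * _WINDOW
            hi = 1_000_000 + (g + 1) * _GENE_SPACING - 3 * _WINDOW
            pos = int(rng.integers(lo, hi))
        else:
            pos = int(rng.integers(1, chrom_len))
        k = 0 if cls == "no_site" else int(rng.choice(config.site_count_choices))
        flank, var_idx = _make_flank(rng, config.flank_len, k)
        allele_a, allele_b = rng.choice(["A", "C", "G", "T"], size=2, replace=False)
        probe_rows.append(
            {
                "snp_id": snp_id,
                "chrom": "chr1",
                "pos": pos,
                "allele_a": allele_a,
                "allele_b": allele_b,
                "flank": flank,
                "variant_index": var_idx,
            }
        )
        methylated = (
            str(rng.choice(["A", "B"]))
            if cls == "cis_asm"
            else ("parental" if cls == "imprinted" else "none")
        )
        truth_rows.append(
            {
                "snp_id": snp_id,
                "class": cls,
                "methylated_allele": methylated,
                "sites_a": k,
                "sites_b": k,
            }
        )
        u = rng.random(config.n_samples)
        for s, us in zip(samples, u):
            if us < config.het_freq:
                call = "AB"
            elif us < config.het_freq + (1 - config.het_freq) / 2:
                call = "AA"
            else:
                call = "BB"
            geno_rows.append({"sample_id": s, "snp_id": snp_id, "call": call})

    return Panel(
        probes=pd.DataFrame(probe_rows),
        loci=loci,
        truth=pd.DataFrame(truth_rows),
        genotypes=pd.DataFrame(geno_rows),
    )


def _sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _lognoise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of
    variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    s = _sigma(cv)
    return np.exp(rng.normal(-0.5 * s * s, s, size=size))


_COPIES = {"AA": (2, 0), "AB": (1, 1), "BB": (0, 2), "NoCall": (1, 1)}


def simulate_intensities(
    probes: pd.DataFrame,
    truth: pd.DataFrame,
    genotypes: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Two-channel intensities for every (sample, probe) in G, D and U.

    Returns a long DataFrame: sample_id, condition, snp_id, intensity_a,
    intensity_b.  Deterministic given the generator state (defaults to
    ``default_rng(config.seed + 1)`` so panel and intensities drawn from
    the same config never share a stream).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    truth_ix = truth.set_index("snp_id")
    geno = genotypes.pivot(index="sample_id", columns="snp_id", values="call")
    samples = list(geno.index)
    ns = len(samples)
    cv_c = config.noise_cv * math.sqrt(config.channel_noise_frac)
    cv_s = config.noise_cv * math.sqrt(1 - config.channel_noise_frac)
    resid = config.residual_uncut

    rows = []
    for _, probe in probes.iterrows():
        snp_id = probe["snp_id"]
        t = truth_ix.loc[snp_id]
        k_a, k_b = int(t["sites_a"]), int(t["sites_b"])
        cls, meth = t["class"], t["methylated_allele"]
        i0 = math.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd))
        i0_u = i0 * math.exp(rng.normal(0.0, config.u_baseline_log_sd)) if (
            config.u_baseline_log_sd > 0
        ) else i0

        shared = _lognoise(rng, cv_s, (ns, 3))
        chan = _lognoise(rng, cv_c, (ns, 3, 2))

        for si, s in enumerate(samples):
            call = geno.loc[s, snp_id]
            c_a, c_b = _COPIES.get(call, (1, 1))
            # copy-level methylation
            if cls == "cis_asm":
                m_a = config.methylation_high if meth == "A" else config.methylation_low
                m_b = config.methylation_high if meth == "B" else config.methylation_low
                surv_a = c_a * (m_a + (1 - m_a) * resid) ** k_a
                surv_b = c_b * (m_b + (1 - m_b) * resid) ** k_b
            elif cls == "imprinted":
                # one of the two chromosome copies methylated, at random
                hi, lo = config.methylation_high, config.methylation_low
                s_hi_a = (hi + (1 - hi) * resid) ** k_a
                s_lo_a = (lo + (1 - lo) * resid) ** k_a
                s_hi_b = (hi + (1 - hi) * resid) ** k_b
                s_lo_b = (lo + (1 - lo) * resid) ** k_b
                if c_a == 2:
                    surv_a, surv_b = s_hi_a + s_lo_a, 0.0
                elif c_b == 2:
                    surv_a, surv_b = 0.0, s_hi_b + s_lo_b
                else:
                    if rng.random() < 0.5:
                        surv_a, surv_b = s_hi_a, s_lo_b
                    else:
                        surv_a, surv_b = s_lo_a, s_hi_b
            elif cls == "null":
                m = config.methylation_high
                surv_a = c_a * (m + (1 - m) * resid) ** k_a
                surv_b = c_b * (m + (1 - m) * resid) ** k_b
            else:  # unmethylated or no_site (k = 0 makes survival 1)
                surv_a = c_a * resid**k_a
                surv_b = c_b * resid**k_b

            u_a = c_a * resid**k_a
            u_b = c_b * resid**k_b
            base = {"G": (i0 * c_a, i0 * c_b), "D": (i0 * surv_a, i0 * surv_b),
                    "U": (i0_u * u_a, i0_u * u_b)}
            for ci, cond in enumerate(("G", "D", "U")):
                ea, eb = base[cond]
                rows.append(
                    {
                        "sample_id": s,
                        "condition": cond,
                        "snp_id": snp_id,
                        "intensity_a": ea * shared[si, ci] * chan[si, ci, 0]
                        + config.background,
                        "intensity_b": eb * shared[si, ci] * chan[si, ci, 1]
                        + config.background,
                    }
                )
    return pd.DataFrame(rows)


def simulate_pyro(
    mean_c: float,
    mean_t: float,
    n_het: int = 4,
    n_hom_c: int = 1,
    n_hom_t: int = 3,
    noise_sd: float = 8.0,
    n_cpg: int = 2,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Per-allele pyrosequencing methylation percentages.

    Each measured allele of each sample gets its planted allele mean plus
    Gaussian noise, truncated to [0, 100].  Heterozygotes contribute both
    alleles per CpG; homozygotes only theirs.  Long format matching the
    packaged fixture: sample_id, genotype, allele, cpg_index,
    methylation_pct.
    """
    if n_het < 2:
        raise ValueError("need at least 2 heterozygotes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    means = {"C": mean_c, "T": mean_t}
    samples = (
        [(f"het{i+1}", "CT", ("C", "T")) for i in range(n_het)]
        + [(f"homC{i+1}", "CC", ("C",)) for i in range(n_hom_c)]
        + [(f"homT{i+1}", "TT", ("T",)) for i in range(n_hom_t)]
    )
    for sample_id, genotype, alleles in samples:
        for cpg in range(1, n_cpg + 1):
            for allele in alleles:
                val = float(
                    np.clip(means[allele] + rng.normal(0.0, noise_sd), 0.0, 100.0)
                ) if noise_sd > 0 else float(np.clip(means[allele], 0.0, 100.0))
                rows.append(
                    {
                        "sample_id": sample_id,
                        "genotype": genotype,
                        "allele": allele,
                        "cpg_index": cpg,
                        "methylation_pct": val,
                    }
                )
    return pd.DataFrame(rows)


def simulate_expression(
    dosage: dict[str, int],
    slope: float,
    intercept: float,
    noise_sd: float,
    gene_name: str = "GENE",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Gene-level FPKM linear in allele dosage with Gaussian noise,
    floored at 0 (expression cannot be negative)."""
    if len(set(dosage.values())) < 2:
        raise ValueError("need at least 2 genotype classes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for sample_id, d in dosage.items():
        noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        rows.append(
            {
                "gene_name": gene_name,
                "sample_id": sample_id,
                "fpkm": max(0.0, intercept + slope * d + noise),
            }
        )
    return pd.DataFrame(rows)
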