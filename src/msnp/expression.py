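"""Genotype-dosage association of neighboring gene expression.

For a candidate ASM SNP, every gene whose body intersects a ±window around
the SNP is regressed: FPKM ~ allele dosage (0/1/2 copies of the alternate
allele) by ordinary least squares, reporting the slope's two-sided p, R²
and adjusted R².  Genes with negligible expression are reported but not
analyzed, mirroring how near-zero-FPKM genes carry dashes in a results
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DosageRegressionResult",
    "genes_in_window",
    "dosage_regression",
    "filter_low_expression",
    "analyze_locus",
]


@dataclass(frozen=True)
class DosageRegressionResult:
    gene_name: str
    n: int
    slope: float
    intercept: float
    p_value: float
    r_squared: float
    adj_r_squared: float
    analyzed: bool

    @classmethod
    def not_analyzed(cls, gene_name: str, n: int) -> "DosageRegressionResult":
        nan = float("nan")
        return cls(gene_name, n, nan, nan, nan, nan, nan, False)


def genes_in_window(
    snp: tuple[str, int], genes: pd.DataFrame, window_bp: int = 500_000
) -> list[str]:
    """Genes whose [start, end] interval intersects pos ± window_bp
    (inclusive, same chromosome).

    ``genes`` needs columns gene_name, chrom, gene_start, gene_end
    (1-based inclusive).
    """
    chrom, pos = snp
    lo, hi = pos - window_bp, pos + window_bp
    hit = genes[
        (genes["chrom"].astype(str) == str(chrom))
        & (genes["gene_start"] <= hi)
        & (genes["gene_end"] >= lo)
    ]
    return list(hit["gene_name"])


def dosage_regression(
    fpkm: dict[str, float] | pd.Series,
    dosage: dict[str, int] | pd.Series,
    gene_name: str = "",
) -> DosageRegressionResult:
    """OLS of expression on additive allele dosage for one gene.

    ``fpkm`` and ``dosage`` are keyed by sample id; only shared samples are
    used.  Requires ≥3 samples spanning ≥2 genotype classes; with a single
    class the gene is returned unanalyzed (the dash row).  Adjusted R² =
    1 − (1 − R²)(n − 1)/(n − 2).
    """
    f = pd.Series(fpkm, dtype=float)
    d = pd.Series(dosage, dtype=float)
    common = f.index.intersection(d.index)
    y = f[common].to_numpy()
    x = d[common].to_numpy()
    n = len(common)
    if len(np.unique(x)) < 2:
        return DosageRegressionResult.not_analyzed(gene_name, n)
    if n < 3:
        raise ValueError("need ≥3 samples for dosage regression")
    if np.ptp(y) == 0:
        # constant expression: no association by definition
        adj = 1 - (n - 1) / (n - 2)
        return DosageRegressionResult(
            gene_name, n, 0.0, float(y[0]), 1.0, 0.0, float(adj), True
        )
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return DosageRegressionResult(
        gene_name=gene_name,
        n=n,
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_squared=r2,
        adj_r_squared=float(adj),
        analyzed=True,
    )


def filter_low_expression(
    expression: pd.DataFrame, min_mean_fpkm: float = 1.0
) -> set[str]:
    """Genes whose mean FPKM across samples reaches ``min_mean_fpkm``."""
    means = expression.groupby("gene_name")["fpkm"].mean()
    return set(means[means >= min_mean_fpkm].index)


def analyze_locus(
    snp: tuple[str, int],
    genes: pd.DataFrame,
    expression: pd.DataFrame,
    dosage: dict[str, int] | pd.Series,
    window_bp: int = 500_000,
    min_mean_fpkm: float = 1.0,
    fdr_bh: bool = False,
) -> pd.DataFrame:
    """Regress every gene within the window around a SNP on its genotype.

    ``expression`` is long format (gene_name, sample_id, fpkm).  Returns one
    row per windowed gene with group means per dosage, p, R², adjusted R²
    and the analyzed flag; sorted by gene start.  ``fdr_bh`` adds a
    Benjamini–Hochberg ``q_value`` column over the analyzed genes (off by
    default: the single-locus design applies no correction).
    """
    names = genes_in_window(snp, genes, window_bp)
    analyzable = filter_low_expression(expression, min_mean_fpkm)
    dosage = pd.Series(dosage, dtype=float)
    rows = []
    order = genes.set_index("gene_name").loc[names, "gene_start"].sort_values()
    for gene in order.index:
        sub = expression[expression["gene_name"] == gene]
        fpkm = sub.set_index("sample_id")["fpkm"]
        common = fpkm.index.intersection(dosage.index)
        group_means = {
            int(k): float(v)
            for k, v in fpkm[common].groupby(dosage[common]).mean().items()
        }
        if gene in analyzable:
            res = dosage_regression(fpkm, dosage, gene)
        else:
            res = DosageRegressionResult.not_analyzed(gene, len(common))
        rows.append(
            {
                "gene_name": gene,
                "n": res.n,
                "mean_fpkm_dosage0": group_means.get(0, float("nan")),
                "mean_fpkm_dosage1": group_means.get(1, float("nan")),
                "mean_fpkm_dosage2": group_means.get(2, float("nan")),
                "slope": res.slope,
                "intercept": res.intercept,
                "p_value": res.p_value,
                "r_squared": res.r_squared,
                "adj_r_squared": res.adj_r_squared,
                "analyzed": res.analyzed,
            }
        )
    report = pd.DataFrame(rows)
    if fdr_bh and len(report):
        report["q_value"] = np.nan
        mask = report["analyzed"] & report["p_value"].notna()
        if mask.any():
            report.loc[mask, "q_value"] = stats.false_discovery_control(
                report.loc[mask, "p_value"].to_numpy()
            )
    return report
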