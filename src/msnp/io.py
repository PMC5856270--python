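"""Readers and writers for the tab-separated table dialects of the pipeline.

All tables are TSV with a header row.  Coordinates are 1-based inclusive
internally; BED input (0-based half-open) is converted at the reader.
Floats are written with a fixed format so that reruns under the same seed
produce byte-identical files.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .candidates import ASMCandidate, SusceptibilityLocus

__all__ = [
    "read_probes",
    "read_intensities",
    "read_genotypes",
    "read_loci",
    "read_loci_bed",
    "read_pyro",
    "read_expression",
    "read_genes",
    "read_dosage",
    "read_flanks_fasta",
    "write_table",
    "candidates_to_frame",
    "load_pyro_rs36221701",
    "load_expression_groups_rs36221701",
    "load_smad3_genes",
    "load_example_loci",
]

_FLOAT_FMT = "%.6g"


def read_probes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    required = {"snp_id", "chrom", "pos", "allele_a", "allele_b", "flank", "variant_index"}
    _require(df, required, path)
    return df


def read_intensities(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "snp_id": str})
    _require(df, {"sample_id", "condition", "snp_id", "intensity_a", "intensity_b"}, path)
    bad = ~df["condition"].isin(["G", "D", "U"])
    if bad.any():
        raise ValueError(f"{path}: unknown conditions {sorted(df.loc[bad, 'condition'].unique())}")
    return df


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "snp_id": str, "call": str})
    _require(df, {"sample_id", "snp_id", "call"}, path)
    return df


def read_loci(path: str | Path) -> list[SusceptibilityLocus]:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "tag_snp": str, "chrom": str})
    _require(df, {"locus_id", "tag_snp", "chrom", "gene_name", "gene_start", "gene_end"}, path)
    return [
        SusceptibilityLocus(
            r.locus_id, r.tag_snp, r.chrom, r.gene_name, int(r.gene_start), int(r.gene_end)
        )
        for r in df.itertuples()
    ]


def read_loci_bed(path: str | Path) -> list[SusceptibilityLocus]:
    """BED (chrom, start, end, name) as loci; 0-based half-open converted
    to 1-based inclusive.  The name column doubles as locus id and gene
    name; no tag-SNP."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "name": str},
    )
    return [
        SusceptibilityLocus(r.name, "", r.chrom, r.name, int(r.start) + 1, int(r.end))
        for r in df.itertuples()
    ]


def read_pyro(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str, "allele": str})
    _require(df, {"sample_id", "genotype", "allele", "cpg_index", "methylation_pct"}, path)
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_name": str, "sample_id": str})
    _require(df, {"gene_name", "sample_id", "fpkm"}, path)
    return df


def read_genes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_name": str, "chrom": str})
    _require(df, {"gene_name", "chrom", "gene_start", "gene_end"}, path)
    return df


def read_dosage(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require(df, {"sample_id", "dosage"}, path)
    return dict(zip(df["sample_id"], df["dosage"].astype(int)))


def read_flanks_fasta(path: str | Path) -> dict[str, str]:
    """Flank sequences keyed by record id (the probe's SNP id)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def candidates_to_frame(candidates: list[ASMCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_id": c.snp_id,
                "delta_ras_bar": c.delta_ras_bar,
                "signed_delta": c.signed_delta,
                "n_het": c.n_het,
                "direction": c.direction,
                "matched_genes": ";".join(f"{g}@{d}" for g, d in c.matched_genes),
                "qc_flags": ";".join(c.qc_flags),
            }
            for c in candidates
        ],
        columns=[
            "snp_id", "delta_ras_bar", "signed_delta", "n_het",
            "direction", "matched_genes", "qc_flags",
        ],
    )


def _require(df: pd.DataFrame, cols: set[str], path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")


def _fixture(name: str) -> Path:
    return resources.files("msnp.data").joinpath(name)  # type: ignore[return-value]


def load_pyro_rs36221701() -> pd.DataFrame:
    """Published per-allele bisulfite-pyrosequencing methylation
    percentages around rs36221701 (4 C/T heterozygotes, 1 C/C, 3 T/T;
    CpG1 and CpG2)."""
    with resources.as_file(_fixture("pyro_rs36221701.tsv")) as p:
        return read_pyro(p)


def load_expression_groups_rs36221701() -> pd.DataFrame:
    """Published per-genotype mean FPKM of the six genes within 500 kbp of
    rs36221701 (group means only; per-sample values were not released)."""
    with resources.as_file(_fixture("expression_groups_rs36221701.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"gene_name": str})
        return df


def load_smad3_genes() -> pd.DataFrame:
    """GRCh37 spans of the six genes around rs36221701 (15:67356489)."""
    with resources.as_file(_fixture("smad3_locus_genes.tsv")) as p:
        return read_genes(p)


def load_example_loci() -> list[SusceptibilityLocus]:
    """A small example susceptibility-locus table (the SMAD3 region)."""
    with resources.as_file(_fixture("example_loci.tsv")) as p:
        return read_loci(p)
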