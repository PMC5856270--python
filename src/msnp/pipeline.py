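"""End-to-end orchestration of the ASM candidate-selection funnel.

``run_pipeline`` takes a :class:`PipelineConfig` whose paths point at the
input tables (or at nothing, in which case a synthetic panel is generated
under the configured seed), runs MSRE gating → RAS statistics → exclusion
criteria → ΔRAS̄ thresholding → locus windowing → quality control, and
writes per-stage counts plus all intermediate tables to the output
directory.  When pyrosequencing or expression inputs are configured the
corresponding validation reports are produced as well.

Every stage reads only the serialized outputs of the previous one, so any
stage can be rerun from disk and reproduces its outputs exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .candidates import CandidateConfig, extract_candidates
from .digest import DEFAULT_ENZYMES, ProbeRecord, probe_site_counts
from .expression import analyze_locus
from .pyro import combined_rank_test, paired_allele_test, per_allele_summary
from .ras import RasConfig, compute_probe_stats
from .simulate import SimulationConfig, simulate_intensities, simulate_panel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "scan_probe_table", "simulate_to_dir"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.

    Leave ``probes``/``intensities``/``genotypes``/``loci`` unset to run on
    a synthetic panel drawn with ``sim`` (seeded).  The pyro and expression
    inputs are optional add-ons.
    """

    output_dir: str | Path = "msnp_out"
    probes: str | Path | None = None
    intensities: str | Path | None = None
    genotypes: str | Path | None = None
    loci: str | Path | None = None
    pyro: str | Path | None = None
    expression: str | Path | None = None
    genes: str | Path | None = None
    dosage: str | Path | None = None
    expr_snp: tuple[str, int] | None = None
    ras: RasConfig = field(default_factory=RasConfig)
    candidate: CandidateConfig = field(default_factory=CandidateConfig)
    expr_window_bp: int = 500_000
    min_mean_fpkm: float = 1.0
    sim: SimulationConfig = field(default_factory=SimulationConfig)


def scan_probe_table(probes: pd.DataFrame) -> pd.DataFrame:
    """Per-allele MSRE site counts for a probe annotation table."""
    rows = []
    for r in probes.itertuples():
        rec = ProbeRecord(
            r.snp_id, str(r.chrom), int(r.pos), r.allele_a, r.allele_b,
            r.flank, int(r.variant_index),
        )
        a, b = probe_site_counts(rec, DEFAULT_ENZYMES)
        rows.append({"snp_id": r.snp_id, "msre_sites_a": a, "msre_sites_b": b})
    return pd.DataFrame(rows)


def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> None:
    """Write a full synthetic input set (probes, loci, genotypes,
    intensities, truth) as the TSV dialects the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = simulate_panel(config)
    intens = simulate_intensities(panel.probes, panel.truth, panel.genotypes, config)
    mio.write_table(panel.probes, outdir / "probes.tsv")
    mio.write_table(panel.truth, outdir / "truth.tsv")
    mio.write_table(panel.genotypes, outdir / "genotypes.tsv")
    mio.write_table(intens, outdir / "intensities.tsv")
    loci_df = pd.DataFrame(
        [
            {
                "locus_id": l.locus_id, "tag_snp": l.tag_snp, "chrom": l.chrom,
                "gene_name": l.gene_name, "gene_start": l.gene_start,
                "gene_end": l.gene_end,
            }
            for l in panel.loci
        ]
    )
    mio.write_table(loci_df, outdir / "loci.tsv")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the funnel; returns the run log (stage counts and output paths)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": {}, "outputs": {}}

    if config.probes is None:
        logger.info("no input tables configured — simulating a panel")
        simulate_to_dir(config.sim, out / "sim_inputs")
        config.probes = out / "sim_inputs" / "probes.tsv"
        config.intensities = out / "sim_inputs" / "intensities.tsv"
        config.genotypes = out / "sim_inputs" / "genotypes.tsv"
        config.loci = out / "sim_inputs" / "loci.tsv"

    for name in ("intensities", "genotypes", "loci"):
        if getattr(config, name) is None:
            raise FileNotFoundError(f"pipeline stage 'inputs': missing {name} table")

    probes = mio.read_probes(config.probes)
    intensities = mio.read_intensities(config.intensities)
    genotypes = mio.read_genotypes(config.genotypes)
    loci_path = Path(config.loci)
    loci = (
        mio.read_loci_bed(loci_path)
        if loci_path.suffix.lower() == ".bed"
        else mio.read_loci(loci_path)
    )

    site_counts = scan_probe_table(probes)
    mio.write_table(site_counts, out / "site_counts.tsv")
    log["outputs"]["site_counts"] = str(out / "site_counts.tsv")

    stats, het_shifts = compute_probe_stats(intensities, genotypes, config.ras)
    mio.write_table(stats, out / "probe_stats.tsv")
    mio.write_table(het_shifts, out / "het_shifts.tsv")
    log["outputs"]["probe_stats"] = str(out / "probe_stats.tsv")

    cands, funnel = extract_candidates(
        stats, het_shifts, site_counts, probes[["snp_id", "chrom", "pos"]],
        loci, config.candidate, config.ras.delta_ras,
    )
    cand_df = mio.candidates_to_frame(cands)
    mio.write_table(cand_df, out / "candidates.tsv")
    funnel_df = pd.DataFrame(
        [{"stage": k, "count": v} for k, v in funnel.items()]
    )
    mio.write_table(funnel_df, out / "funnel.tsv")
    log["stages"] = funnel
    log["outputs"]["candidates"] = str(out / "candidates.tsv")

    if config.pyro is not None:
        pyro = mio.read_pyro(config.pyro)
        rows = []
        for cpg in sorted(pyro["cpg_index"].unique()):
            het = per_allele_summary(pyro, cpg, "het_only")
            t, df_, p_t = paired_allele_test(pyro, cpg)
            alls = per_allele_summary(pyro, cpg, "all")
            u, p_u = combined_rank_test(pyro, cpg)
            rows.append(
                {
                    "cpg_index": cpg,
                    "het_mean_c": het.mean_c, "het_sd_c": het.sd_c, "het_n_c": het.n_c,
                    "het_mean_t": het.mean_t, "het_sd_t": het.sd_t, "het_n_t": het.n_t,
                    "paired_t": t, "paired_df": df_, "paired_p": p_t,
                    "all_mean_c": alls.mean_c, "all_n_c": alls.n_c,
                    "all_mean_t": alls.mean_t, "all_n_t": alls.n_t,
                    "rank_sum_u": u, "rank_sum_p": p_u,
                }
            )
        mio.write_table(pd.DataFrame(rows), out / "pyro_report.tsv")
        log["outputs"]["pyro_report"] = str(out / "pyro_report.tsv")

    if config.expression is not None:
        if config.genes is None or config.dosage is None or config.expr_snp is None:
            raise FileNotFoundError(
                "pipeline stage 'expression': needs genes, dosage and expr_snp"
            )
        expr = mio.read_expression(config.expression)
        genes = mio.read_genes(config.genes)
        dosage = mio.read_dosage(config.dosage)
        report = analyze_locus(
            config.expr_snp, genes, expr, dosage,
            config.expr_window_bp, config.min_mean_fpkm,
        )
        mio.write_table(report, out / "expression_report.tsv")
        log["outputs"]["expression_report"] = str(out / "expression_report.tsv")

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
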