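"""Generative models: determinism, expectation identities, planted truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from msnp.pipeline import scan_probe_table, simulate_to_dir
from msnp.pyro import paired_allele_test
from msnp.ras import compute_ras
from msnp.simulate import (
    SimulationConfig,
    simulate_expression,
    simulate_intensities,
    simulate_panel,
    simulate_pyro,
)


def _single_probe(cls, sites=1, n_het=4, alleles=("A", "C"), meth="A"):
    probes = pd.DataFrame(
        [{"snp_id": "p0", "chrom": "chr1", "pos": 100, "allele_a": alleles[0],
          "allele_b": alleles[1], "flank": "T" * 71, "variant_index": 35}]
    )
    truth = pd.DataFrame(
        [{"snp_id": "p0", "class": cls,
          "methylated_allele": meth if cls == "cis_asm" else
          ("parental" if cls == "imprinted" else "none"),
          "sites_a": sites, "sites_b": sites}]
    )
    geno = pd.DataFrame(
        [{"sample_id": f"s{i}", "snp_id": "p0", "call": "AB"} for i in range(n_het)]
    )
    return probes, truth, geno


class TestSimulatePanel:
    def test_deterministic_under_fixed_seed(self, default_config):
        a = simulate_panel(default_config)
        b = simulate_panel(default_config)
        pd.testing.assert_frame_equal(a.probes, b.probes)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)

    def test_zero_asm_fraction(self):
        cfg = SimulationConfig(n_probes=200, asm_fraction=0.0, seed=2)
        panel = simulate_panel(cfg)
        assert (panel.truth["class"] != "cis_asm").all()

    def test_class_counts_within_binomial_interval(self, panel):
        n, p = 1000, 0.05
        lo, hi = sps.binom.ppf([0.025, 0.975], n, p)
        count = int((panel.truth["class"] == "cis_asm").sum())
        assert lo <= count <= hi

    def test_fractions_summing_over_one_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(asm_fraction=0.6, imprint_fraction=0.6)

    def test_flanks_reproduce_truth_site_counts(self, panel):
        counts = scan_probe_table(panel.probes.head(80))
        merged = counts.merge(panel.truth, on="snp_id")
        assert (merged["msre_sites_a"] == merged["sites_a"]).all()
        assert (merged["msre_sites_b"] == merged["sites_b"]).all()

    def test_emitted_files_byte_identical_across_reruns(self, tmp_path):
        cfg = SimulationConfig(n_probes=30, n_samples=4, seed=9)
        simulate_to_dir(cfg, tmp_path / "a")
        simulate_to_dir(cfg, tmp_path / "b")
        for name in ("probes.tsv", "truth.tsv", "genotypes.tsv",
                     "intensities.tsv", "loci.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()


class TestIntensityModel:
    def test_full_asm_limit_reproduces_call_conversion(self):
        """Complete one-allele methylation, no residual cutting, no
        background: a heterozygote reads 0.5 in G and 1.0 in D — the
        AB → AA call conversion."""
        cfg = SimulationConfig(methylation_high=1.0, methylation_low=0.0,
                               residual_uncut=0.0, background=0.0,
                               noise_cv=0.0, u_baseline_log_sd=0.0, seed=0)
        probes, truth, geno = _single_probe("cis_asm", meth="A")
        intens = simulate_intensities(probes, truth, geno, cfg)
        g = intens[intens["condition"] == "G"]
        d = intens[intens["condition"] == "D"]
        for _, row in g.iterrows():
            assert compute_ras(row["intensity_a"], row["intensity_b"]) == 0.5
        for _, row in d.iterrows():
            assert compute_ras(row["intensity_a"], row["intensity_b"]) == 1.0

    def test_no_site_probe_conditions_agree(self):
        cfg = SimulationConfig(noise_cv=0.0, background=0.0,
                               u_baseline_log_sd=0.0, seed=0)
        probes, truth, geno = _single_probe("no_site", sites=0)
        intens = simulate_intensities(probes, truth, geno, cfg)
        wide = intens.pivot_table(index="sample_id", columns="condition",
                                  values="intensity_a")
        assert np.allclose(wide["G"], wide["D"])
        assert np.allclose(wide["G"], wide["U"])

    def test_unmethylated_probe_matches_residual_expectation(self):
        cfg = SimulationConfig(noise_cv=0.0, background=0.0,
                               u_baseline_log_sd=0.0, residual_uncut=0.05, seed=0)
        probes, truth, geno = _single_probe("unmethylated", sites=1)
        intens = simulate_intensities(probes, truth, geno, cfg)
        wide = intens.pivot_table(index="sample_id", columns="condition",
                                  values="intensity_a")
        assert np.allclose(wide["D"] / wide["G"], 0.05)
        assert np.allclose(wide["U"], wide["D"])

    def test_survival_expectation_identities(self):
        """E[D]/E[G] is 1 for a fully methylated allele and
        residual_uncut^k for a fully unmethylated one."""
        cfg = SimulationConfig(methylation_high=1.0, methylation_low=0.0,
                               residual_uncut=0.05, noise_cv=0.0,
                               background=0.0, u_baseline_log_sd=0.0, seed=0)
        probes, truth, geno = _single_probe("cis_asm", sites=2, meth="A")
        intens = simulate_intensities(probes, truth, geno, cfg)
        g = intens[intens["condition"] == "G"].iloc[0]
        d = intens[intens["condition"] == "D"].iloc[0]
        assert d["intensity_a"] / g["intensity_a"] == pytest.approx(1.0)
        assert d["intensity_b"] / g["intensity_b"] == pytest.approx(0.05**2)

    def test_imprinted_homozygote_loses_half_signal(self):
        cfg = SimulationConfig(methylation_high=1.0, methylation_low=0.0,
                               residual_uncut=0.0, noise_cv=0.0,
                               background=0.0, u_baseline_log_sd=0.0, seed=0)
        probes, truth, _ = _single_probe("imprinted", sites=1)
        geno = pd.DataFrame(
            [{"sample_id": "s0", "snp_id": "p0", "call": "AA"}]
        )
        intens = simulate_intensities(probes, truth, geno, cfg)
        g = intens[intens["condition"] == "G"].iloc[0]
        d = intens[intens["condition"] == "D"].iloc[0]
        assert d["intensity_a"] / g["intensity_a"] == pytest.approx(0.5)


class TestSimulatePyro:
    def test_noise_free_planted_means(self):
        df = simulate_pyro(80.0, 65.0, noise_sd=0.0)
        assert (df.loc[df["allele"] == "C", "methylation_pct"] == 80).all()
        assert (df.loc[df["allele"] == "T", "methylation_pct"] == 65).all()

    def test_structure_matches_cohort_layout(self):
        df = simulate_pyro(80, 65, n_het=4, n_hom_c=1, n_hom_t=3)
        assert df["sample_id"].nunique() == 8
        het_rows = df[df["genotype"] == "CT"]
        assert len(het_rows) == 4 * 2 * 2  # both alleles, both CpGs

    def test_degenerate_equal_alleles_exercises_paired_test(self):
        df = simulate_pyro(70.0, 70.0, noise_sd=0.0)
        with pytest.warns(UserWarning):
            t, _, p = paired_allele_test(df, 1)
        assert t == 0 and p == 1.0

    def test_rejection_rate_matches_noncentral_t_power(self):
        """Paired-t power at a planted 15-point allele difference with
        noise sd 8 and 4 heterozygotes, against the closed form."""
        rng = np.random.default_rng(77)
        n_het, diff, sd, reps = 4, 15.0, 8.0, 500
        rejected = 0
        for _ in range(reps):
            df = simulate_pyro(80.0, 80.0 - diff, n_het=n_het, n_hom_c=0,
                               n_hom_t=0, noise_sd=sd, n_cpg=1, seed=rng)
            _, _, p = paired_allele_test(df, 1)
            rejected += p < 0.05
        ncp = diff / (sd * np.sqrt(2) / np.sqrt(n_het))
        tcrit = sps.t.ppf(0.975, n_het - 1)
        power = sps.nct.sf(tcrit, n_het - 1, ncp) + sps.nct.cdf(-tcrit, n_het - 1, ncp)
        assert rejected / reps == pytest.approx(power, abs=0.07)

    def test_too_few_heterozygotes_rejected(self):
        with pytest.raises(ValueError):
            simulate_pyro(80, 65, n_het=1)


class TestSimulateExpression:
    def test_noise_free_group_means(self):
        dosage = {f"s{i}": d for i, d in enumerate([0] * 6 + [1] * 4 + [2])}
        expr = simulate_expression(dosage, 38.28, 43.91, 0.0)
        means = expr.set_index("sample_id")["fpkm"].groupby(pd.Series(dosage)).mean()
        assert list(means.round(2)) == [43.91, 82.19, 120.47]

    def test_never_negative(self):
        dosage = {f"s{i}": i % 3 for i in range(30)}
        expr = simulate_expression(dosage, -50.0, 10.0, 100.0, seed=3)
        assert (expr["fpkm"] >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression({"a": 1, "b": 1}, 1.0, 0.0, 1.0)
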