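"""RAS arithmetic, exclusion criteria and ΔRAS̄."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msnp.ras import (
    RasConfig,
    apply_exclusion_criteria,
    compute_probe_stats,
    compute_ras,
    condition_means,
    delta_ras_bar,
    exclusion_ratios,
)

pos_intensity = st.floats(0.01, 1e6, allow_nan=False)


class TestComputeRas:
    @pytest.mark.parametrize(
        "a, b, expected", [(500, 500, 0.5), (800, 0, 1.0), (30, 70, 0.3)]
    )
    def test_values(self, a, b, expected):
        assert compute_ras(a, b) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compute_ras(0, 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            compute_ras(-1, 5)

    @given(pos_intensity, pos_intensity)
    def test_complement_identity(self, a, b):
        assert compute_ras(a, b) + compute_ras(b, a) == pytest.approx(1.0)


class TestConditionMeans:
    def test_mean_over_samples(self):
        df = pd.DataFrame({"intensity_a": [100, 300], "intensity_b": [300, 100]})
        assert condition_means(df) == (200, 200)

    def test_single_sample_identity(self):
        df = pd.DataFrame({"intensity_a": [50], "intensity_b": [70]})
        assert condition_means(df) == (50, 70)

    def test_zero_channel(self):
        df = pd.DataFrame({"intensity_a": [10, 20, 30], "intensity_b": [0, 0, 0]})
        assert condition_means(df) == (20, 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            condition_means(pd.DataFrame({"intensity_a": [], "intensity_b": []}))


class TestExclusionCriteria:
    def test_identity_ratios(self):
        assert exclusion_ratios((1000, 1000), (1000, 1000), (1000, 1000)) == (1.0, 1.0)

    def test_collinear(self):
        rg, rd = exclusion_ratios((1200, 0), (600, 0), (100, 0))
        assert (rg, rd) == (12.0, 6.0)

    def test_three_four_five_norm(self):
        rg, _ = exclusion_ratios((300, 400), (300, 400), (30, 40))
        assert rg == pytest.approx(10.0)

    def test_zero_u_distance_rejected(self):
        with pytest.raises(ValueError):
            exclusion_ratios((1, 1), (1, 1), (0, 0))

    @pytest.mark.parametrize(
        "rg, rd, expected",
        [(1.0, 5.0, "criterion1"), (5.0, 1.0, "criterion2"), (5.0, 5.0, "keep"),
         (1.19, 1.19, "criterion1")],
    )
    def test_classification(self, rg, rd, expected):
        assert apply_exclusion_criteria(rg, rd) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            apply_exclusion_criteria(float("nan"), 1.0)


class TestDeltaRasBar:
    def test_no_change(self):
        res = delta_ras_bar([(0.5, 0.5), (0.5, 0.5)])
        assert (res.delta_ras_bar, res.signed_delta, res.n_het) == (0.0, 0.0, 2)
        assert res.evaluable and not res.is_asm

    def test_uniform_shift(self):
        res = delta_ras_bar([(0.5, 0.8)] * 4)
        assert res.delta_ras_bar == pytest.approx(0.3)
        assert res.signed_delta == pytest.approx(0.3)
        assert res.is_asm

    def test_imprinting_signature(self):
        """Opposite shifts: high magnitude mean, zero signed mean."""
        res = delta_ras_bar([(0.5, 0.8), (0.5, 0.2)])
        assert res.delta_ras_bar == pytest.approx(0.3)
        assert res.signed_delta == pytest.approx(0.0)

    def test_below_min_het_not_evaluable(self):
        res = delta_ras_bar([(0.5, 0.9)])
        assert not res.evaluable and not res.is_asm and res.n_het == 1

    @given(
        st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=2, max_size=12
        )
    )
    def test_bounds_and_triangle_inequality(self, pairs):
        res = delta_ras_bar(pairs)
        assert 0 <= res.delta_ras_bar <= 1
        assert abs(res.signed_delta) <= res.delta_ras_bar + 1e-12

    @given(
        st.lists(
            st.tuples(st.floats(0, 1), st.floats(0, 1)), min_size=2, max_size=12
        )
    )
    def test_allele_relabeling(self, pairs):
        """A↔B swap maps every RAS to 1−RAS: ΔRAS̄ invariant, sign flips."""
        res = delta_ras_bar(pairs)
        flipped = delta_ras_bar([(1 - g, 1 - d) for g, d in pairs])
        assert flipped.delta_ras_bar == pytest.approx(res.delta_ras_bar)
        assert flipped.signed_delta == pytest.approx(-res.signed_delta)


def naive_probe_stats(intensities: pd.DataFrame, genotypes: pd.DataFrame) -> dict:
    """Brute-force oracle for per-probe statistics, written with plain loops."""
    out = {}
    for snp_id in sorted(intensities["snp_id"].unique()):
        sub = intensities[intensities["snp_id"] == snp_id]
        means = {}
        for cond in "GDU":
            rows = sub[sub["condition"] == cond]
            means[cond] = (
                sum(rows["intensity_a"]) / len(rows),
                sum(rows["intensity_b"]) / len(rows),
            )
        du = math.hypot(*means["U"])
        rg = math.hypot(*means["G"]) / du
        rd = math.hypot(*means["D"]) / du
        hets = genotypes[
            (genotypes["snp_id"] == snp_id) & (genotypes["call"] == "AB")
        ]["sample_id"]
        diffs = []
        for s in hets:
            g = sub[(sub["condition"] == "G") & (sub["sample_id"] == s)].iloc[0]
            d = sub[(sub["condition"] == "D") & (sub["sample_id"] == s)].iloc[0]
            ras_g = g["intensity_a"] / (g["intensity_a"] + g["intensity_b"])
            ras_d = d["intensity_a"] / (d["intensity_a"] + d["intensity_b"])
            diffs.append(ras_d - ras_g)
        out[snp_id] = {
            "ratio_g_u": rg,
            "ratio_d_u": rd,
            "delta_ras_bar": sum(abs(x) for x in diffs) / len(diffs) if diffs else None,
            "signed_delta": sum(diffs) / len(diffs) if diffs else None,
            "n_het": len(diffs),
        }
    return out


class TestComputeProbeStats:
    def _random_tables(self, rng, n_probes=6, n_samples=5):
        samples = [f"s{i}" for i in range(n_samples)]
        snps = [f"p{i}" for i in range(n_probes)]
        rows = [
            {
                "sample_id": s,
                "condition": c,
                "snp_id": p,
                "intensity_a": rng.uniform(10, 2000),
                "intensity_b": rng.uniform(10, 2000),
            }
            for p in snps
            for s in samples
            for c in "GDU"
        ]
        geno = [
            {"sample_id": s, "snp_id": p, "call": rng.choice(["AA", "AB", "BB", "NoCall"])}
            for p in snps
            for s in samples
        ]
        return pd.DataFrame(rows), pd.DataFrame(geno)

    def test_agrees_with_brute_force_on_random_tables(self, rng):
        intens, geno = self._random_tables(rng)
        stats, _ = compute_probe_stats(intens, geno, RasConfig(min_het=1))
        oracle = naive_probe_stats(intens, geno)
        for _, row in stats.iterrows():
            exp = oracle[row["snp_id"]]
            assert row["ratio_g_u"] == pytest.approx(exp["ratio_g_u"])
            assert row["ratio_d_u"] == pytest.approx(exp["ratio_d_u"])
            assert row["n_het"] == exp["n_het"]
            if exp["delta_ras_bar"] is not None:
                assert row["delta_ras_bar"] == pytest.approx(exp["delta_ras_bar"])
                assert row["signed_delta"] == pytest.approx(exp["signed_delta"])

    def test_global_allele_relabeling_flips_sign(self, rng):
        intens, geno = self._random_tables(rng)
        stats, _ = compute_probe_stats(intens, geno, RasConfig(min_het=1))
        swapped = intens.rename(
            columns={"intensity_a": "intensity_b", "intensity_b": "intensity_a"}
        )
        stats_sw, _ = compute_probe_stats(swapped, geno, RasConfig(min_het=1))
        merged = stats.merge(stats_sw, on="snp_id", suffixes=("", "_sw"))
        assert np.allclose(merged["delta_ras_bar"], merged["delta_ras_bar_sw"], equal_nan=True)
        ok = merged["evaluable"]
        assert np.allclose(
            merged.loc[ok, "signed_delta"], -merged.loc[ok, "signed_delta_sw"]
        )

    def test_zero_denominator_records_dropped_per_record(self, caplog):
        intens = pd.DataFrame(
            [
                {"sample_id": s, "condition": c, "snp_id": "p0",
                 "intensity_a": 0.0 if (s == "s0" and c == "D") else 100.0,
                 "intensity_b": 0.0 if (s == "s0" and c == "D") else 100.0}
                for s in ["s0", "s1", "s2"]
                for c in "GDU"
            ]
        )
        geno = pd.DataFrame(
            [{"sample_id": s, "snp_id": "p0", "call": "AB"} for s in ["s0", "s1", "s2"]]
        )
        stats, shifts = compute_probe_stats(intens, geno)
        # s0's D record is invalid; the other two heterozygotes remain
        assert stats.iloc[0]["n_het"] == 2
        assert set(shifts["sample_id"]) == {"s1", "s2"}


class TestMedianScaling:
    def test_scaling_preserves_ras_and_equalizes_array_medians(self, rng):
        from msnp.ras import median_scale_arrays

        intens, _ = TestComputeProbeStats()._random_tables(rng, n_probes=8)
        # inflate one array by a large factor
        sel = (intens["sample_id"] == "s0") & (intens["condition"] == "G")
        intens.loc[sel, ["intensity_a", "intensity_b"]] *= 9.0
        scaled = median_scale_arrays(intens)
        total = scaled["intensity_a"] + scaled["intensity_b"]
        med = total.groupby([scaled["sample_id"], scaled["condition"]]).median()
        assert med.max() / med.min() < 3  # arrays brought to a common scale
        # RAS is scale-free, so per-record RAS is unchanged
        r_before = intens["intensity_a"] / (intens["intensity_a"] + intens["intensity_b"])
        r_after = scaled["intensity_a"] / total
        assert np.allclose(r_before, r_after)
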