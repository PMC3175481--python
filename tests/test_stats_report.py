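"""Rank tests against exhaustive enumeration, the familywise correction,
strand-bias ratios, the contrast battery, and the TSS metaprofile."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import (
    oracle_mwu_distribution,
    oracle_mwu_two_sided,
    oracle_wilcoxon_two_sided,
)
from pirte import stats_report as sr
from pirte.annotation_io import RteLocus, TssRecord, loci_frame
from pirte.locus_grouping import AGE_GROUPS, LOCATION_GROUPS


class TestWilcoxon:
    def test_six_positive_pairs_exact(self):
        stat, p, n, under = sr.wilcoxon_signed_rank_paired(
            [2.0, 3.0, 4.0, 5.0, 6.0, 7.0], [1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
        )
        assert p == pytest.approx(2 / 2**6)
        assert n == 6 and not under

    def test_symmetric_differences_give_p_one(self):
        _, p, _, _ = sr.wilcoxon_signed_rank_paired([1.0, -1.0], [0.0, 0.0])
        assert p == 1.0

    def test_all_zero_differences_flagged(self):
        stat, p, n, under = sr.wilcoxon_signed_rank_paired([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0 and n == 0 and under

    def test_matches_enumeration_for_all_sign_patterns(self):
        """Every sign pattern at n = 5..10 (distinct magnitudes)."""
        for n in range(5, 11):
            mags = np.arange(1.0, n + 1.0)
            for pattern in range(1, 2**n - 1):
                signs = np.array(
                    [1 if pattern >> i & 1 else -1 for i in range(n)], dtype=float
                )
                d = mags * signs
                _, p, _, _ = sr.wilcoxon_signed_rank_paired(d)
                assert p == pytest.approx(oracle_wilcoxon_two_sided(d), abs=1e-12), (
                    n, pattern,
                )


class TestMannWhitney:
    def test_extreme_separation_exact(self):
        u, p = sr.mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(2 / math.comb(6, 3))

    def test_identical_groups(self):
        _, p = sr.mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            sr.mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("n_a,n_b", [(3, 3), (4, 4), (5, 5), (8, 8), (3, 8)])
    def test_matches_enumeration_for_every_achievable_u(self, n_a, n_b):
        """The exact p is a function of U alone (no ties); compare the
        implementation with the partition-enumeration oracle at every U."""
        counts = oracle_mwu_distribution(n_a, n_b)
        pooled = list(range(1, n_a + n_b + 1))
        for u_obs in sorted(counts):
            # construct a sample achieving this U: move u_obs "wins" into a
            a = []
            remaining = u_obs
            for i in range(n_a):
                wins = min(n_b, remaining)
                remaining -= wins
                a.append(wins)
            # a[i] wins means a-value bigger than 'wins' smallest b-values
            b_vals = [10 * (j + 1) for j in range(n_b)]
            a_vals = [10 * w + 5 + 0.1 * i for i, w in enumerate(a)]  # tie-free
            u_check = sum(1 for x in a_vals for y in b_vals if x > y)
            assert u_check == u_obs
            u, p = sr.mann_whitney_u(a_vals, b_vals)
            assert u == u_obs
            assert p == pytest.approx(oracle_mwu_two_sided(u_obs, counts), abs=1e-12)


class TestCorrectP:
    def test_closed_form_value(self):
        assert sr.correct_p(0.05, 108) == pytest.approx(1 - 0.95**108, abs=1e-10)
        assert round(sr.correct_p(0.05, 108), 4) == 0.9961

    def test_boundaries(self):
        assert sr.correct_p(0.0, 50) == 0.0
        assert sr.correct_p(1.0, 50) == 1.0
        assert sr.correct_p(0.3, 1) == pytest.approx(0.3)

    def test_monotone_in_p_and_n(self):
        ps = np.linspace(0.0, 1.0, 41)
        for n in (1, 2, 10, 108, 1000):
            vals = [sr.correct_p(p, n) for p in ps]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
        for p in (1e-9, 1e-4, 0.01, 0.5):
            vals = [sr.correct_p(p, n) for n in (1, 2, 5, 50, 108, 1000)]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
            assert all(v >= p for v in vals)

    def test_stable_for_tiny_p(self):
        # Series expansion: 1-(1-p)^n = np - C(n,2)p^2 + O(p^3)
        p, n = 1e-12, 108
        expected = n * p - math.comb(n, 2) * p**2
        assert sr.correct_p(p, n) == pytest.approx(expected, rel=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sr.correct_p(-0.1, 10)
        with pytest.raises(ValueError):
            sr.correct_p(1.1, 10)


class TestStrandBias:
    def test_exact_ratio_without_pseudocount(self):
        assert sr.strand_bias(4, 1, pseudocount=0) == pytest.approx(2.0)

    def test_symmetry_and_zero_handling(self):
        assert sr.strand_bias(7, 7) == 0.0
        assert sr.strand_bias(0, 0) == 0.0  # pseudocount keeps it finite

    def test_aggregation_sums_counts_before_ratio(self):
        loci = loci_frame(
            [
                RteLocus(f"L{i}", "chr1", i * 1000, i * 1000 + 100, "+", "f", "s", "LINE", 1.0)
                for i in range(3)
            ]
        )
        cov = pd.DataFrame(
            {"unique_sense": [4, 0, 2], "unique_antisense": [0, 1, 1]}, index=loci.index
        )
        rel = pd.Series(["forward", "forward", "nongenic"], index=loci.index)
        out = sr.strand_bias_table(cov, loci, rel, "lib").set_index("category")
        assert out.loc["forward", "unique_sense"] == 4
        assert out.loc["forward", "log2_ratio"] == pytest.approx(
            np.log2(4.5 / 1.5)
        )


def _battery_frame(n_families=6, effect=0.0, rng=None, libraries=("lib1",)):
    rng = rng or np.random.default_rng(0)
    rows = []
    for lib in libraries:
        for rte_type in ("LINE", "SINE", "LTRint", "LTRter"):
            for fam in range(n_families):
                for age in AGE_GROUPS:
                    base = rng.random() + 1.0
                    for loc in LOCATION_GROUPS:
                        bump = effect if loc == "proximal" else 0.0
                        rows.append(
                            {
                                "family": f"{rte_type}_f{fam}",
                                "rte_type": rte_type,
                                "library": lib,
                                "age_group": age,
                                "location_group": loc,
                                "mean_coverage": base + bump + rng.normal(0, 0.01),
                            }
                        )
    return pd.DataFrame(rows)


class TestBattery:
    def test_full_battery_has_108_rows(self):
        nine = _battery_frame(libraries=("a", "b", "c"))
        out = sr.figure5_battery(nine)
        assert len(out) == 108
        assert out["n_correction"].iloc[0] == 108

    def test_correction_n_defaults_to_contrasts_run(self):
        nine = _battery_frame(libraries=("a",))
        out = sr.figure5_battery(nine)
        assert len(out) == 36 and out["n_correction"].iloc[0] == 36
        forced = sr.figure5_battery(nine, n_correction=108)
        assert forced["n_correction"].iloc[0] == 108
        assert (forced["p_corrected"] >= out["p_corrected"] - 1e-12).all()

    def test_planted_effect_detected_with_direction(self):
        nine = _battery_frame(n_families=16, effect=1.0, libraries=("a", "b", "c"))
        out = sr.figure5_battery(nine)
        pd_rows = out[(out["group_a"] == "proximal") & (out["group_b"] == "distal")]
        assert (pd_rows["direction"] == "greater").all()
        assert (pd_rows["significance_tier"] != "ns").all()

    def test_missing_cells_drop_pairs_and_flag_underpowered(self):
        nine = _battery_frame(n_families=4, libraries=("a",))
        nine.loc[nine["location_group"] == "distal", "mean_coverage"] = np.nan
        out = sr.figure5_battery(nine)
        distal_rows = out[out["group_b"] == "distal"]
        assert (distal_rows["n_families"] == 0).all()
        assert (distal_rows["significance_tier"] == "ns").all()
        assert distal_rows["underpowered"].all()

    def test_p_corrected_consistent_with_formula(self):
        nine = _battery_frame(libraries=("a", "b", "c"))
        out = sr.figure5_battery(nine)
        for _, row in out.head(20).iterrows():
            assert row["p_corrected"] == pytest.approx(
                sr.correct_p(row["p_raw"], int(row["n_correction"])), abs=1e-12
            )


class TestProximalFraction:
    def _assignments(self, families):
        rows = []
        for fam, (young_spec, old_spec) in families.items():
            for age, spec in (("young", young_spec), ("old", old_spec)):
                n_prox, n_other = spec
                for i in range(n_prox):
                    rows.append((fam, age, "proximal"))
                for i in range(n_other):
                    rows.append((fam, age, "distal"))
        df = pd.DataFrame(rows, columns=["family", "age_group", "location_group"])
        df.index = [f"x{i}" for i in range(len(df))]
        return df

    def test_young_higher_fraction(self):
        # distinct positive young-old differences -> exact signed-rank p
        fams = {f"f{i}": ((9 - i, 1 + i), (1 + i, 9 - i)) for i in range(4)}
        fams.update({f"g{i}": ((8, 4 + i), (2, 10 + i)) for i in range(2)})
        frac, p, n = sr.proximal_fraction_comparison(self._assignments(fams))
        assert frac == 1.0 and n == 6
        assert p == pytest.approx(2 / 2**6)

    def test_tied_family_excluded_from_numerator(self):
        fams = {"f1": ((5, 5), (5, 5)), "f2": ((8, 2), (2, 8)), "f3": ((8, 2), (2, 8))}
        frac, _, n = sr.proximal_fraction_comparison(self._assignments(fams))
        assert n == 3
        assert frac == pytest.approx(2 / 3)

    def test_nongenic_denominator_option(self):
        fams = {f"f{i}": ((4, 4), (2, 6)) for i in range(4)}
        a = self._assignments(fams)
        frac_all, _, _ = sr.proximal_fraction_comparison(a, denominator="all")
        frac_ng, _, _ = sr.proximal_fraction_comparison(a, denominator="nongenic")
        assert frac_all == frac_ng == 1.0


class TestTssProfile:
    def _mappings(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "multiplicity"])
        df["read_id"] = [f"r{i}" for i in range(len(df))]
        df["weight"] = 1.0 / df["multiplicity"]
        return df

    def test_read_at_tss_lands_in_bin_zero_sense(self):
        tss = [TssRecord("g", "chr1", 5000, "+")]
        m = self._mappings([("chr1", 5000, 5026, "+", 1)])
        prof = sr.tss_profile(m, tss, loci_frame([]), half_width=2000, bin_size=10)
        row = prof[prof["offset"] == 0].iloc[0]
        assert row["sense_nonrte"] == 1.0
        assert prof[["sense_rte", "antisense_rte", "antisense_nonrte"]].sum().sum() == 0

    def test_minus_strand_gene_orientation(self):
        """On a '-' gene, a '+' read 100 bp left of the TSS is downstream
        (offset +100) on the antisense track."""
        tss = [TssRecord("g", "chr1", 5000, "-")]
        m = self._mappings([("chr1", 4900, 4926, "+", 1)])
        prof = sr.tss_profile(m, tss, loci_frame([]), half_width=2000, bin_size=10)
        row = prof[prof["offset"] == 100].iloc[0]
        assert row["antisense_nonrte"] == 1.0

    def test_rte_mappings_tracked_separately(self):
        tss = [TssRecord("g", "chr1", 5000, "+")]
        loci = loci_frame(
            [RteLocus("L", "chr1", 5500, 6000, "+", "f", "s", "LINE", 1.0)]
        )
        m = self._mappings(
            [("chr1", 5600, 5626, "+", 2), ("chr1", 4000, 4026, "-", 1)]
        )
        prof = sr.tss_profile(m, tss, loci, half_width=2000, bin_size=10)
        assert prof["sense_rte"].sum() == pytest.approx(0.5)
        assert prof["antisense_nonrte"].sum() == pytest.approx(1.0)

    def test_profile_total_is_weighted_in_window_mass(self):
        tss = [TssRecord("g", "chr1", 5000, "+")]
        m = self._mappings(
            [
                ("chr1", 5000 + d, 5026 + d, "+", mult)
                for d, mult in ((-1500, 1), (0, 2), (500, 4), (50_000, 1))
            ]
        )
        prof = sr.tss_profile(m, tss, loci_frame([]), half_width=2000, bin_size=10)
        total = prof[["sense_rte", "sense_nonrte", "antisense_rte", "antisense_nonrte"]].sum().sum()
        assert total == pytest.approx(1 + 0.5 + 0.25)

    def test_half_width_must_align_with_bin(self):
        with pytest.raises(ValueError):
            sr.tss_profile(self._mappings([]), [], loci_frame([]), half_width=1995, bin_size=10)
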