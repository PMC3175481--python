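"""Weighted coverage: containment assignment, normalization, exclusivity
scopes, unique-strand counts, family summaries."""

import numpy as np
import pandas as pd
import pytest

from pirte import coverage_engine as ce
from pirte.annotation_io import RteLocus, loci_frame
from pirte.read_processing import ReadMappingSet


def make_locus(locus_id="L1", chrom="chr1", start=0, end=100, strand="+",
               family="famA", superfamily="sfA", rte_type="LINE", millidiv=10.0):
    return RteLocus(locus_id, chrom, start, end, strand, family, superfamily, rte_type, millidiv)


def ms(read_id, length, mappings):
    return ReadMappingSet(read_id, length, mappings)


class TestAssignment:
    def test_containment_rule(self):
        loci = loci_frame([make_locus(start=0, end=100)])
        sets = [
            ms("inside", 26, [("chr1", 10, "+")]),
            ms("straddle", 26, [("chr1", 90, "+")]),
            ms("other_chrom", 26, [("chr2", 10, "+")]),
        ]
        mdf = ce.mappings_frame(sets)
        assign = ce.assign_reads_to_loci(mdf, loci)
        assigned_reads = set(mdf.iloc[assign["mapping_row"]]["read_id"])
        assert assigned_reads == {"inside"}

    def test_any_overlap_mode_includes_straddlers(self):
        loci = loci_frame([make_locus(start=0, end=100)])
        mdf = ce.mappings_frame([ms("straddle", 26, [("chr1", 90, "+")])])
        assign = ce.assign_reads_to_loci(mdf, loci, mode="any")
        assert len(assign) == 1

    def test_overlapping_loci_both_receive_the_mapping(self):
        loci = loci_frame(
            [make_locus("A", start=0, end=100), make_locus("B", start=20, end=120)]
        )
        mdf = ce.mappings_frame([ms("r", 26, [("chr1", 30, "+")])])
        assign = ce.assign_reads_to_loci(mdf, loci)
        assert sorted(assign["locus_id"]) == ["A", "B"]

    def test_flat_and_tree_paths_agree(self, rng):
        # Random non-overlapping loci: force the generic path by adding a
        # decoy overlapping pair on another chromosome.
        loci_list = []
        pos = 0
        for i in range(30):
            pos += int(rng.integers(30, 120))
            end = pos + int(rng.integers(40, 150))
            loci_list.append(make_locus(f"L{i}", start=pos, end=end))
            pos = end
        flat = loci_frame(loci_list)
        with_decoy = loci_frame(
            loci_list
            + [make_locus("D1", chrom="chr9", start=0, end=50),
               make_locus("D2", chrom="chr9", start=10, end=60)]
        )
        sets = [
            ms(f"r{j}", 26, [("chr1", int(rng.integers(0, pos)), "+")])
            for j in range(200)
        ]
        mdf = ce.mappings_frame(sets)
        a = ce.assign_reads_to_loci(mdf, flat)
        b = ce.assign_reads_to_loci(mdf, with_decoy)
        b = b[~b["locus_id"].isin(["D1", "D2"])]
        key = lambda df: sorted(zip(df["mapping_row"], df["locus_id"]))
        assert key(a) == key(b)


class TestLocusCoverage:
    def test_hand_example(self):
        """2 kb locus, two unique reads plus one 4-fold multimapper with one
        inside mapping, library of 500k reads -> coverage 2.25."""
        locus = make_locus(start=1000, end=3000)
        sets = [
            ms("u1", 26, [("chr1", 1100, "+")]),
            ms("u2", 26, [("chr1", 1200, "-")]),
            ms("m4", 26, [("chr1", 1300, "+"), ("chr1", 9000, "+"),
                          ("chr2", 10, "+"), ("chr2", 500, "-")]),
        ]
        mdf = ce.mappings_frame(sets)
        loci = loci_frame([locus])
        assign = ce.assign_reads_to_loci(mdf, loci)
        assigned = mdf.iloc[assign["mapping_row"]]
        cov = ce.locus_coverage(locus, assigned, library_size_reads=500_000)
        assert cov.raw_weighted_count == pytest.approx(2.25)
        assert cov.coverage == pytest.approx(2.25 / 2.0 / 0.5)
        assert (cov.unique_sense, cov.unique_antisense) == (1, 1)

    def test_no_reads_zero_coverage(self):
        locus = make_locus()
        cov = ce.locus_coverage(locus, ce.mappings_frame([]), 1000)
        assert cov.raw_weighted_count == 0.0 and cov.coverage == 0.0

    def test_doubling_the_library_cancels(self):
        locus = make_locus(start=0, end=1000)
        base = [ms("a", 26, [("chr1", 10, "+")])]
        doubled = base + [ms("b", 26, [("chr1", 10, "+")])]
        loci = loci_frame([locus])
        covs = []
        for sets, size in ((base, 100), (doubled, 200)):
            mdf = ce.mappings_frame(sets)
            assign = ce.assign_reads_to_loci(mdf, loci)
            covs.append(
                ce.locus_coverage(locus, mdf.iloc[assign["mapping_row"]], size).coverage
            )
        assert covs[0] == pytest.approx(covs[1])

    def test_zero_length_locus_is_an_error(self):
        with pytest.raises(Exception):
            make_locus(start=5, end=5)


class TestExclusivity:
    def _loci(self):
        return loci_frame(
            [
                make_locus("L1a", start=0, end=200, family="famA", superfamily="sfA"),
                make_locus("L1b", start=300, end=500, family="famA", superfamily="sfA"),
                make_locus("L2a", start=600, end=800, family="famB", superfamily="sfA"),
                make_locus("L3a", start=900, end=1100, family="famC", superfamily="sfC"),
            ]
        )

    def test_scope_hierarchy(self):
        loci = self._loci()
        sets = [
            # all mappings within famA loci
            ms("in_famA", 26, [("chr1", 10, "+"), ("chr1", 310, "+")]),
            # famA and famB loci: superfamily-exclusive (sfA) only
            ms("in_sfA", 26, [("chr1", 10, "+"), ("chr1", 610, "+")]),
            # one mapping outside any locus
            ms("leaky", 26, [("chr1", 10, "+"), ("chr1", 2000, "+")]),
        ]
        by_scope = lambda scope, name: {
            s.read_id for s in ce.exclusive_subset(sets, loci, scope, name)
        }
        assert by_scope("family", "famA") == {"in_famA"}
        assert by_scope("superfamily", "sfA") == {"in_famA", "in_sfA"}
        assert by_scope("family", "famC") == set()

    def test_subset_nesting(self):
        """family-exclusive reads are a subset of superfamily-exclusive."""
        loci = self._loci()
        rng = np.random.default_rng(0)
        sets = []
        for i in range(100):
            n_map = int(rng.integers(1, 4))
            mappings = []
            for _ in range(n_map):
                start = int(rng.integers(0, 1200))
                mappings.append(("chr1", start, "+"))
            sets.append(ms(f"r{i}", 26, sorted(set(mappings))))
        fam = {s.read_id for s in ce.exclusive_subset(sets, loci, "family", "famA")}
        sf = {s.read_id for s in ce.exclusive_subset(sets, loci, "superfamily", "sfA")}
        assert fam <= sf

    def test_multiplicity_preserved(self):
        loci = self._loci()
        sets = [ms("r", 26, [("chr1", 10, "+"), ("chr1", 310, "-")])]
        (kept,) = ce.exclusive_subset(sets, loci, "family", "famA")
        assert kept.multiplicity == 2

    def test_unknown_scope_name(self):
        with pytest.raises(ValueError):
            ce.exclusive_subset([], self._loci(), "family", "nope")


class TestUniqueStrand:
    def test_sense_antisense_and_multimapper_exclusion(self):
        locus = make_locus(start=0, end=100, strand="+")
        sets = [
            ms("u_plus", 26, [("chr1", 5, "+")]),
            ms("u_minus", 26, [("chr1", 10, "-")]),
            ms("multi", 26, [("chr1", 20, "+"), ("chr1", 400, "+")]),
        ]
        mdf = ce.mappings_frame(sets)
        loci = loci_frame([locus])
        assign = ce.assign_reads_to_loci(mdf, loci)
        sense, anti = ce.unique_strand_coverage(locus, mdf.iloc[assign["mapping_row"]])
        assert (sense, anti) == (1, 1)


class TestGenicFraction:
    def _cov(self, raws):
        loci = loci_frame(
            [make_locus(f"L{i}", start=i * 200, end=i * 200 + 100) for i in range(len(raws))]
        )
        cov = pd.DataFrame(
            {"raw_weighted_count": raws, "locus_id": loci["locus_id"]}, index=loci.index
        )
        return loci, cov

    def test_arithmetic(self):
        loci, cov = self._cov([3.0, 1.0])
        location = pd.Series(["genic", "distal"], index=loci.index)
        frac, locus_frac = ce.genic_coverage_fraction(cov, location, loci, "LINE")
        assert frac == pytest.approx(0.75)
        assert locus_frac == pytest.approx(0.5)

    def test_zero_genic(self):
        loci, cov = self._cov([2.0, 2.0])
        location = pd.Series(["distal", "proximal"], index=loci.index)
        frac, locus_frac = ce.genic_coverage_fraction(cov, location, loci, "LINE")
        assert frac == 0.0 and locus_frac == 0.0

    def test_zero_total_coverage_reported_missing(self):
        loci, cov = self._cov([0.0, 0.0])
        location = pd.Series(["genic", "distal"], index=loci.index)
        frac, _ = ce.genic_coverage_fraction(cov, location, loci, "LINE")
        assert frac is None


class TestFamilySummary:
    def _cov_df(self, families, coverages):
        loci = loci_frame(
            [
                make_locus(f"L{i}", start=i * 200, end=i * 200 + 100, family=f,
                           superfamily="sf", rte_type="LINE")
                for i, f in enumerate(families)
            ]
        )
        cov = pd.DataFrame(
            {
                "coverage": coverages,
                "raw_weighted_count": coverages,
                "library": "lib",
            },
            index=loci.index,
        )
        return loci, cov

    def test_min_loci_excludes_small_families(self):
        loci, cov = self._cov_df(["a"] * 5 + ["b"] * 2, list(range(7)))
        out = ce.family_summary(cov, loci, min_loci=3)
        assert list(out["family"]) == ["a"]

    def test_constant_family_degenerate_percentiles(self):
        loci, cov = self._cov_df(["a"] * 4, [3.0] * 4)
        out = ce.family_summary(cov, loci, min_loci=1)
        row = out.iloc[0]
        assert row["median_coverage"] == row["mean_coverage"] == row["p25"] == row["p75"] == 3.0

    def test_indexed_mean_max_scaling(self):
        loci, cov = self._cov_df(["a"] * 3 + ["b"] * 3, [2.0] * 3 + [8.0] * 3)
        out = ce.family_summary(cov, loci, min_loci=1).set_index("family")
        assert out.loc["a", "indexed_mean"] == pytest.approx(0.25)
        assert out.loc["b", "indexed_mean"] == pytest.approx(1.0)


class TestLibraryCorrelation:
    def test_rank_invariance_and_signs(self):
        a = pd.Series([1.0, 2.0, 3.0], index=["f1", "f2", "f3"])
        assert ce.library_correlation(a, a) == pytest.approx(1.0)
        assert ce.library_correlation(a, a.iloc[::-1].set_axis(a.index)) == pytest.approx(-1.0)
        monotone = pd.Series([2.0, 4.0, 9.0], index=a.index)
        assert ce.library_correlation(a, monotone) == pytest.approx(1.0)

    def test_requires_three_shared_families(self):
        a = pd.Series([1.0, 2.0], index=["f1", "f2"])
        with pytest.raises(ValueError):
            ce.library_correlation(a, a)


class TestAgainstSmallSimulation:
    def test_pipeline_matches_per_read_oracle(self, small_sim):
        """Per-locus weighted counts equal an independent re-enumeration."""
        from conftest import oracle_locus_raw
        from pirte.read_processing import GenomeIndex, map_reads

        cfg, bundle, libraries = small_sim
        index = GenomeIndex(bundle.genome, k=16)
        lib = libraries[1]
        mapped, _ = map_reads(index, lib.reads[:2000])
        mdf = ce.mappings_frame(mapped)
        loci_df = loci_frame(bundle.loci)
        cov = ce.coverage_table(loci_df, mdf, len(mapped)).set_index("locus_id")
        rng = np.random.default_rng(1)
        sample = rng.choice(len(bundle.loci), size=25, replace=False)
        for i in sample:
            locus = bundle.loci[i]
            assert cov.loc[locus.locus_id, "raw_weighted_count"] == pytest.approx(
                oracle_locus_raw(mdf, locus), abs=1e-9
            )

    def test_weight_conservation_upper_bound(self, small_sim):
        cfg, bundle, libraries = small_sim
        from pirte.read_processing import GenomeIndex, map_reads

        index = GenomeIndex(bundle.genome, k=16)
        mapped, _ = map_reads(index, libraries[0].reads)
        mdf = ce.mappings_frame(mapped)
        loci_df = loci_frame(bundle.loci)
        cov = ce.coverage_table(loci_df, mdf, len(mapped))
        assert cov["raw_weighted_count"].sum() <= len(mapped) + 1e-9
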