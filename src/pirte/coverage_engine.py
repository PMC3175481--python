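"""Weighted per-locus piRNA coverage.

The central statistic: for each RTE locus, sum 1/(genomic mapping count)
over the read mappings contained in the locus, then normalize per kb of
locus and per million mapped library reads.  Also provides
superfamily/family-exclusive read subsets, strand-resolved unique-read
counts, genic coverage fractions and family-level summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class LocusCoverage:
    locus_id: str
    library: str
    raw_weighted_count: float
    coverage: float
    unique_sense: int
    unique_antisense: int


def mappings_frame(mapping_sets) -> pd.DataFrame:
    """Flatten mapping sets into one row per (read, mapping).

    Columns: read_id, chrom, start, end, strand, multiplicity, weight.
    """
    rows = {
        "read_id": [],
        "chrom": [],
        "start": [],
        "end": [],
        "strand": [],
        "multiplicity": [],
    }
    for ms in mapping_sets:
        for chrom, start, strand in ms.mappings:
            rows["read_id"].append(ms.read_id)
            rows["chrom"].append(chrom)
            rows["start"].append(start)
            rows["end"].append(start + ms.length)
            rows["strand"].append(strand)
            rows["multiplicity"].append(ms.multiplicity)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(
            columns=["read_id", "chrom", "start", "end", "strand", "multiplicity", "weight"]
        )
        return df.astype({"start": int, "end": int, "multiplicity": int, "weight": float})
    df["weight"] = 1.0 / df["multiplicity"]
    return df


class LocusIndex:
    """Containment/overlap queries from mappings to loci.

    When the loci of a chromosome are mutually non-overlapping a sorted-
    array binary search answers containment in O(log n); otherwise an
    interval tree handles the general case.  Both paths return identical
    results (property-tested).
    """

    def __init__(self, loci_df: pd.DataFrame):
        self.loci = loci_df
        self._flat: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for chrom, grp in loci_df.groupby("chrom", sort=True):
            grp = grp.sort_values(["start", "end"], kind="stable")
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            idx = grp.index.to_numpy()
            if np.all(starts[1:] >= ends[:-1]):
                self._flat[chrom] = (starts, ends, idx)
            else:
                tree = IntervalTree()
                for s, e, i in zip(starts, ends, idx):
                    tree.addi(int(s), int(e), i)
                self._trees[chrom] = tree

    def containing(self, chrom: str, start: int, end: int) -> list:
        """Locus ids whose interval fully contains [start, end)."""
        if chrom in self._flat:
            starts, ends, idx = self._flat[chrom]
            i = int(np.searchsorted(starts, start, side="right")) - 1
            if i >= 0 and ends[i] >= end:
                return [idx[i]]
            return []
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [
            iv.data for iv in sorted(tree.overlap(start, end))
            if iv.begin <= start and iv.end >= end
        ]

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        if chrom in self._flat:
            starts, ends, idx = self._flat[chrom]
            lo = int(np.searchsorted(ends, start, side="right"))
            hi = int(np.searchsorted(starts, end, side="left"))
            return list(idx[lo:hi])
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in sorted(tree.overlap(start, end))]

    def query(self, chrom: str, start: int, end: int, mode: str = "contained") -> list:
        if mode == "contained":
            return self.containing(chrom, start, end)
        if mode == "any":
            return self.overlapping(chrom, start, end)
        raise ValueError("mode must be 'contained' or 'any'")


def assign_reads_to_loci(
    mappings: pd.DataFrame, loci_df: pd.DataFrame, mode: str = "contained"
) -> pd.DataFrame:
    """Assign each mapping row to the loci containing it.

    Returns a frame with columns (mapping_row, locus_id); one read may feed
    several loci through different mappings, and a mapping contained in two
    overlapping loci feeds both.
    """
    index = LocusIndex(loci_df)
    if mode == "contained" and not index._trees:
        # All chromosomes non-overlapping: containment is one binary search.
        frames = []
        flat_mappings = mappings.reset_index(drop=True)
        for chrom, grp in flat_mappings.groupby("chrom", sort=True):
            flat = index._flat.get(chrom)
            if flat is None:
                continue
            l_starts, l_ends, l_idx = flat
            m_start = grp["start"].to_numpy()
            m_end = grp["end"].to_numpy()
            i = np.searchsorted(l_starts, m_start, side="right") - 1
            ok = (i >= 0) & (l_ends[np.clip(i, 0, None)] >= m_end)
            rows = grp.index.to_numpy()
            frames.append(
                pd.DataFrame({"mapping_row": rows[ok], "locus_id": l_idx[i[ok]]})
            )
        if frames:
            return pd.concat(frames, ignore_index=True)
        return pd.DataFrame({"mapping_row": [], "locus_id": []})
    rows = []
    hits = []
    chroms = mappings["chrom"].to_numpy()
    starts = mappings["start"].to_numpy()
    ends = mappings["end"].to_numpy()
    for i in range(len(mappings)):
        for locus_id in index.query(chroms[i], starts[i], ends[i], mode=mode):
            rows.append(i)
            hits.append(locus_id)
    return pd.DataFrame({"mapping_row": rows, "locus_id": hits})


def locus_coverage(
    locus, assigned_mappings: pd.DataFrame, library_size_reads: int, library: str = ""
) -> LocusCoverage:
    """Coverage of one locus from the mappings assigned to it.

    raw = sum of 1/multiplicity; coverage = raw / (length/1000)
    / (library_size/1e6).  Unique sense/antisense counts consider only
    multiplicity-1 reads; sense means the mapping strand equals the locus
    strand.
    """
    if library_size_reads <= 0:
        raise ValueError("library size must be positive")
    length = locus.end - locus.start
    if length <= 0:
        raise ValueError(f"{locus.locus_id}: zero-length locus (annotation bug)")
    raw = float(assigned_mappings["weight"].sum()) if len(assigned_mappings) else 0.0
    unique = assigned_mappings[assigned_mappings["multiplicity"] == 1]
    sense = int((unique["strand"] == locus.strand).sum())
    antisense = len(unique) - sense
    return LocusCoverage(
        locus_id=locus.locus_id,
        library=library,
        raw_weighted_count=raw,
        coverage=raw / (length / 1000.0) / (library_size_reads / 1e6),
        unique_sense=sense,
        unique_antisense=antisense,
    )


def coverage_table(
    loci_df: pd.DataFrame,
    mappings: pd.DataFrame,
    library_size_reads: int,
    library: str = "",
    mode: str = "contained",
) -> pd.DataFrame:
    """Per-locus coverage for every locus (zeros included).

    Returns a frame indexed by locus_id with raw_weighted_count, coverage,
    unique_sense, unique_antisense, library.
    """
    if library_size_reads <= 0:
        raise ValueError("library size must be positive")
    n = len(loci_df)
    raw = pd.Series(0.0, index=loci_df.index)
    u_sense = pd.Series(0, index=loci_df.index)
    u_anti = pd.Series(0, index=loci_df.index)
    if len(mappings):
        assign = assign_reads_to_loci(mappings, loci_df, mode=mode)
        if len(assign):
            m = mappings.iloc[assign["mapping_row"].to_numpy()].reset_index(drop=True)
            m["locus_id"] = assign["locus_id"].to_numpy()
            raw = raw.add(m.groupby("locus_id")["weight"].sum(), fill_value=0.0)
            uniq = m[m["multiplicity"] == 1].copy()
            if len(uniq):
                uniq["locus_strand"] = loci_df.loc[uniq["locus_id"], "strand"].to_numpy()
                sense_mask = uniq["strand"] == uniq["locus_strand"]
                u_sense = u_sense.add(
                    uniq[sense_mask].groupby("locus_id").size(), fill_value=0
                ).astype(int)
                u_anti = u_anti.add(
                    uniq[~sense_mask].groupby("locus_id").size(), fill_value=0
                ).astype(int)
    out = pd.DataFrame(
        {
            "locus_id": loci_df["locus_id"],
            "library": library,
            "raw_weighted_count": raw,
            "unique_sense": u_sense,
            "unique_antisense": u_anti,
        }
    )
    out["coverage"] = (
        out["raw_weighted_count"]
        / (loci_df["length"] / 1000.0)
        / (library_size_reads / 1e6)
    )
    assert len(out) == n
    return out[
        ["locus_id", "library", "raw_weighted_count", "coverage", "unique_sense", "unique_antisense"]
    ]


def exclusivity(mapping_sets, loci_df: pd.DataFrame) -> dict[str, tuple[frozenset, frozenset]]:
    """Per-read exclusivity scopes.

    For each read id: the set of superfamilies (and of families) such that
    *every* genomic mapping of the read is contained in a locus of that
    scope; empty set when no scope qualifies.  Multiplicities stay the
    genome-wide counts — the weight is a property of the read.
    """
    index = LocusIndex(loci_df)
    sf_col = loci_df["superfamily"]
    fam_col = loci_df["family"]
    out: dict[str, tuple[frozenset, frozenset]] = {}
    for ms in mapping_sets:
        sf_set: set | None = None
        fam_set: set | None = None
        for chrom, start, strand in ms.mappings:
            ids = index.containing(chrom, start, start + ms.length)
            sfs = {sf_col[i] for i in ids}
            fams = {fam_col[i] for i in ids}
            sf_set = sfs if sf_set is None else (sf_set & sfs)
            fam_set = fams if fam_set is None else (fam_set & fams)
            if not sf_set and not fam_set:
                break
        out[ms.read_id] = (frozenset(sf_set or ()), frozenset(fam_set or ()))
    return out


def exclusive_subset(mapping_sets, loci_df: pd.DataFrame, scope: str, name: str):
    """Reads whose every mapping lies within a locus of the given scope.

    ``scope`` is 'superfamily' or 'family'; multiplicities are preserved.
    """
    if scope not in ("superfamily", "family"):
        raise ValueError("scope must be 'superfamily' or 'family'")
    if name not in set(loci_df[scope]):
        raise ValueError(f"unknown {scope} {name!r}")
    sub = loci_df[loci_df[scope] == name]
    index = LocusIndex(sub)
    kept = []
    for ms in mapping_sets:
        if ms.mapped and all(
            index.containing(chrom, start, start + ms.length)
            for chrom, start, _ in ms.mappings
        ):
            kept.append(ms)
    return kept


def unique_strand_coverage(locus, assigned_mappings: pd.DataFrame) -> tuple[int, int]:
    """(unique_sense, unique_antisense) for one locus."""
    unique = assigned_mappings[assigned_mappings["multiplicity"] == 1]
    sense = int((unique["strand"] == locus.strand).sum())
    return sense, len(unique) - sense


def genic_coverage_fraction(
    cov: pd.DataFrame, location: pd.Series, loci_df: pd.DataFrame, rte_type: str
) -> tuple[float | None, float]:
    """Fraction of a type's total weighted coverage on genic loci, plus the
    fraction of loci that are genic."""
    ids = loci_df.index[loci_df["rte_type"] == rte_type]
    if len(ids) == 0:
        return None, float("nan")
    raw = cov.loc[ids, "raw_weighted_count"]
    genic_ids = [i for i in ids if location.get(i) == "genic"]
    total = float(raw.sum())
    locus_fraction = len(genic_ids) / len(ids)
    if total == 0:
        return None, locus_fraction
    return float(raw.loc[genic_ids].sum()) / total, locus_fraction


def family_summary(
    cov: pd.DataFrame, loci_df: pd.DataFrame, min_loci: int = 1000
) -> pd.DataFrame:
    """Family-level coverage and age summaries over ALL member loci.

    Families with fewer than ``min_loci`` genomic members are excluded.
    ``indexed_mean`` rescales mean coverage so the top family within each
    RTE type sits at 1.
    """
    df = cov.join(loci_df[["family", "rte_type", "millidiv"]])
    rows = []
    for (family, rte_type), grp in df.groupby(["family", "rte_type"], sort=True):
        if len(grp) < min_loci:
            continue
        c = grp["coverage"].to_numpy()
        m = grp["millidiv"].to_numpy()
        rows.append(
            {
                "family": family,
                "rte_type": rte_type,
                "library": grp["library"].iloc[0],
                "n_loci": len(grp),
                "median_coverage": float(np.median(c)),
                "mean_coverage": float(np.mean(c)),
                "p25": float(np.percentile(c, 25)),
                "p75": float(np.percentile(c, 75)),
                "median_millidiv": float(np.median(m)),
                "p25_millidiv": float(np.percentile(m, 25)),
                "p75_millidiv": float(np.percentile(m, 75)),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "family", "rte_type", "library", "n_loci", "median_coverage", "mean_coverage",
            "p25", "p75", "median_millidiv", "p25_millidiv", "p75_millidiv",
        ],
    )
    if len(out):
        out["indexed_mean"] = out.groupby("rte_type")["mean_coverage"].transform(
            lambda s: s / s.max() if s.max() > 0 else 0.0
        )
    else:
        out["indexed_mean"] = pd.Series(dtype=float)
    return out


def library_correlation(
    medians_a: pd.Series, medians_b: pd.Series, method: str = "spearman"
) -> float:
    """Rank correlation of per-family medians between two libraries."""
    shared = medians_a.index.intersection(medians_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared families")
    a = medians_a.loc[shared].to_numpy()
    b = medians_b.loc[shared].to_numpy()
    if method == "spearman":
        rho = stats.spearmanr(a, b).statistic
    elif method == "pearson":
        rho = stats.pearsonr(a, b).statistic
    else:
        raise ValueError("method must be 'spearman' or 'pearson'")
    return float(rho)
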