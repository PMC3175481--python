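"""Within-family grouping of RTE loci by age and genomic location.

Each family's loci are split into three equally sized age tertiles
(young/median/old, by millidivergence) and, independently, into
genic/proximal/distal location classes.  Genic membership is decided by the
locus midpoint falling inside a gene span; for non-genic loci the
proximal/distal border is the family-specific median of distances to the
nearest gene.  Also builds the gene-context datasets: isolated genes,
expression quartile groups, RTE coverage in TSS-to-stop windows, and the
intronic composition summary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

AGE_GROUPS = ("young", "median", "old")
LOCATION_GROUPS = ("genic", "proximal", "distal")


def tertile_sizes(n: int) -> tuple[int, int, int]:
    """Sizes of the young/median/old groups for a family of n loci.

    Equal thirds; remainder loci go to the earlier (younger) groups, so the
    sizes differ by at most one.
    """
    base, rem = divmod(n, 3)
    return tuple(base + (1 if i < rem else 0) for i in range(3))


def assign_age_groups(family_loci: pd.DataFrame) -> pd.Series:
    """Age tertile per locus of ONE family (needs >= 3 loci).

    Loci are ordered by (millidiv, locus_id) — the id tie-break keeps the
    split deterministic when divergences tie.
    """
    n = len(family_loci)
    if n < 3:
        raise ValueError("family needs at least 3 loci for age tertiles")
    ordered = family_loci.sort_values(["millidiv", "locus_id"]).index
    sizes = tertile_sizes(n)
    labels = np.repeat(AGE_GROUPS, sizes)
    return pd.Series(labels, index=ordered, name="age_group").reindex(family_loci.index)


def _gene_spans(genes) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in by_chrom.items()}


def gene_distance(chrom: str, midpoint: int, spans: dict[str, np.ndarray]) -> float:
    """Distance from a point to the nearest gene span edge; 0 if inside;
    inf when the chromosome has no genes."""
    arr = spans.get(chrom)
    if arr is None or len(arr) == 0:
        return float("inf")
    starts, ends = arr[:, 0], arr[:, 1]
    inside = (starts <= midpoint) & (midpoint < ends)
    if inside.any():
        return 0.0
    left = midpoint - (ends - 1)
    right = starts - midpoint
    d = np.where(midpoint >= ends, left, np.where(midpoint < starts, right, 0))
    return float(d[d >= 0].min()) if (d >= 0).any() else float("inf")


def classify_location(
    family_loci: pd.DataFrame, genes
) -> tuple[pd.Series, pd.Series, float]:
    """Location class per locus of ONE family.

    Returns (location_group, distance_to_gene, family_median_distance).
    Genic: midpoint inside any gene span.  Non-genic loci at distance <=
    the family median of non-genic distances are proximal, the rest distal.
    Distances are midpoint-to-span-edge.
    """
    spans = _gene_spans(genes)
    mids = family_loci["midpoint"]
    dist = pd.Series(
        [gene_distance(c, m, spans) for c, m in zip(family_loci["chrom"], mids)],
        index=family_loci.index,
        name="distance_to_gene",
    )
    genic = dist == 0.0
    nongenic_dist = dist[~genic]
    location = pd.Series("genic", index=family_loci.index, name="location_group")
    if len(nongenic_dist):
        if np.isinf(nongenic_dist).all():
            warnings.warn("no genes reachable: all non-genic loci classed distal")
            median = float("inf")
            location[~genic] = "distal"
        else:
            median = float(np.median(nongenic_dist))
            location[~genic] = np.where(nongenic_dist <= median, "proximal", "distal")
    else:
        median = float("nan")
    dist[genic] = np.nan
    return location, dist, median


def group_assignments(loci_df: pd.DataFrame, genes, min_family_size: int = 3) -> pd.DataFrame:
    """Age and location groups for every locus, computed family by family.

    Families below ``min_family_size`` are skipped (with a warning).
    Returns a frame indexed by locus_id with age_group, location_group,
    distance_to_gene, family_median_distance, gene_relative_strand.
    """
    frames = []
    skipped = []
    for family, grp in loci_df.groupby("family", sort=True):
        if len(grp) < min_family_size:
            skipped.append(family)
            continue
        age = assign_age_groups(grp)
        location, dist, median = classify_location(grp, genes)
        sub = pd.DataFrame(
            {
                "locus_id": grp["locus_id"],
                "family": family,
                "rte_type": grp["rte_type"],
                "age_group": age,
                "location_group": location,
                "distance_to_gene": dist,
                "family_median_distance": median,
            }
        )
        frames.append(sub)
    if skipped:
        warnings.warn(f"skipped {len(skipped)} family/families below {min_family_size} loci")
    if not frames:
        return pd.DataFrame(
            columns=[
                "locus_id", "family", "rte_type", "age_group", "location_group",
                "distance_to_gene", "family_median_distance", "gene_relative_strand",
            ]
        )
    out = pd.concat(frames)
    out["gene_relative_strand"] = _relative_strands(loci_df.loc[out.index], genes, out["location_group"])
    return out


def gene_relative_strand(locus, genes) -> str:
    """'forward' when a genic locus lies on its host gene's strand.

    The host is the gene whose span contains the locus midpoint; nested
    spans resolve to the innermost (then smallest gene_id).  Calling this
    for a non-genic locus is an error.
    """
    mid = locus.midpoint if hasattr(locus, "midpoint") else (locus.start + locus.end) // 2
    candidates = [
        g for g in genes if g.chrom == locus.chrom and g.start <= mid < g.end
    ]
    if not candidates:
        raise ValueError(f"{locus.locus_id}: not genic")
    host = min(candidates, key=lambda g: (g.end - g.start, g.gene_id))
    if len(candidates) > 1:
        log.info("%s: nested host genes, using innermost %s", locus.locus_id, host.gene_id)
    return "forward" if locus.strand == host.strand else "reverse"


def _relative_strands(loci_df: pd.DataFrame, genes, location: pd.Series) -> pd.Series:
    out = pd.Series("nongenic", index=loci_df.index, name="gene_relative_strand")
    genic_ids = location.index[location == "genic"]
    for locus_id in genic_ids:
        out[locus_id] = gene_relative_strand(loci_df.loc[locus_id], genes)
    return out


def nine_group_means(
    coverage: pd.Series, assignments: pd.DataFrame, family: str
) -> pd.DataFrame:
    """3x3 matrix of mean coverage for one family (age x location).

    Empty cells are NaN (missing, not zero).
    """
    sub = assignments[assignments["family"] == family]
    df = pd.DataFrame(
        {
            "age_group": sub["age_group"],
            "location_group": sub["location_group"],
            "coverage": coverage.loc[sub.index],
        }
    )
    table = (
        df.groupby(["age_group", "location_group"], sort=False)["coverage"]
        .mean()
        .unstack()
    )
    return table.reindex(index=list(AGE_GROUPS), columns=list(LOCATION_GROUPS))


def all_nine_group_means(coverage: pd.Series, assignments: pd.DataFrame) -> pd.DataFrame:
    """Long-form family x age x location mean coverage (NaN for empty cells)."""
    df = assignments[["family", "rte_type", "age_group", "location_group"]].copy()
    df["coverage"] = coverage.loc[df.index]
    means = (
        df.groupby(["family", "rte_type", "age_group", "location_group"], sort=True)[
            "coverage"
        ]
        .mean()
        .reset_index()
    )
    full = []
    for (family, rte_type), grp in means.groupby(["family", "rte_type"], sort=True):
        grid = grp.set_index(["age_group", "location_group"])["coverage"]
        for age in AGE_GROUPS:
            for loc in LOCATION_GROUPS:
                full.append(
                    {
                        "family": family,
                        "rte_type": rte_type,
                        "age_group": age,
                        "location_group": loc,
                        "mean_coverage": grid.get((age, loc), np.nan),
                    }
                )
    return pd.DataFrame(full)


def select_isolated_genes(genes, min_gap: int = 20_000) -> list:
    """Genes whose span is >= min_gap from every other gene span (both
    sides; a missing neighbour counts as satisfied; overlap is gap 0)."""
    kept = []
    for g in genes:
        ok = True
        for other in genes:
            if other is g or other.chrom != g.chrom:
                continue
            gap = max(other.start - g.end, g.start - other.end, 0)
            if (other.start < g.end and other.end > g.start) or gap < min_gap:
                ok = False
                break
        if ok:
            kept.append(g)
    return kept


def expression_groups(genes) -> pd.Series:
    """High/medium/low expression quartile per gene.

    The top and bottom quarters (floor(n/4) each) are high and low; ties at
    a quartile boundary fall into the medium group, so group sizes can
    deviate from exact quarters.
    """
    ids = [g.gene_id for g in genes]
    signals = np.array([g.expression for g in genes], dtype=float)
    if np.isnan(signals).any():
        raise ValueError("expression missing for some genes")
    n = len(genes)
    out = pd.Series("medium", index=ids, name="expression_group")
    q = n // 4
    if q == 0:
        return out
    s = np.sort(signals)
    low_cut = s[q]  # strictly below -> low
    high_cut = s[n - 1 - q]  # strictly above -> high
    out[signals < low_cut] = "low"
    out[signals > high_cut] = "high"
    return out


@dataclass
class GeneWindowCoverage:
    gene_id: str
    expression_group: str
    rte_type: str
    rte_bp_in_window: int
    raw_weighted_count: float
    normalized_coverage: float | None


def gene_window(gene, flank: int = 10_000) -> tuple[int, int]:
    """Genomic window from ``flank`` upstream of the TSS to ``flank`` past
    the stop site, in transcriptional orientation."""
    if gene.strand == "+":
        return gene.tss - flank, gene.end + flank
    return gene.start - flank, gene.tss + 1 + flank


def gene_window_coverage(
    gene,
    loci_df: pd.DataFrame,
    raw_counts: pd.Series,
    library_size_reads: int,
    flank: int = 10_000,
    expression_group: str = "",
    chrom_length: int | None = None,
) -> list[GeneWindowCoverage]:
    """RTE coverage around one gene, per RTE type.

    Loci are collected by midpoint-in-window; the normalizer is the number
    of RTE base pairs (window overlap) of that type, per kb, and the
    library size in millions.  Types with zero RTE bp report a missing
    coverage.
    """
    w0, w1 = gene_window(gene, flank)
    if w0 < 0:
        log.info("%s: window clipped at chromosome start", gene.gene_id)
        w0 = 0
    if chrom_length is not None and w1 > chrom_length:
        log.info("%s: window clipped at chromosome end", gene.gene_id)
        w1 = chrom_length
    sub = loci_df[
        (loci_df["chrom"] == gene.chrom)
        & (loci_df["midpoint"] >= w0)
        & (loci_df["midpoint"] < w1)
    ]
    results = []
    for rte_type, grp in sub.groupby("rte_type", sort=True):
        overlap = (
            np.minimum(grp["end"].to_numpy(), w1) - np.maximum(grp["start"].to_numpy(), w0)
        ).clip(min=0)
        bp = int(overlap.sum())
        raw = float(raw_counts.loc[grp.index].sum())
        cov = None
        if bp > 0:
            cov = raw / (bp / 1000.0) / (library_size_reads / 1e6)
        results.append(
            GeneWindowCoverage(
                gene_id=gene.gene_id,
                expression_group=expression_group,
                rte_type=rte_type,
                rte_bp_in_window=bp,
                raw_weighted_count=raw,
                normalized_coverage=cov,
            )
        )
    return results


def intronic_composition(loci_df: pd.DataFrame, location: pd.Series) -> pd.Series:
    """Fraction of genic RTE base pairs per RTE type (sums to 1)."""
    genic = loci_df.loc[location.index[location == "genic"]]
    if genic.empty:
        return pd.Series(dtype=float, name="genic_bp_fraction")
    bp = genic.groupby("rte_type")["length"].sum()
    out = bp / bp.sum()
    out.name = "genic_bp_fraction"
    return out
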