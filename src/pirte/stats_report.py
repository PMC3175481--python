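"""Statistical testing and figure-style summaries.

Implements the paired Wilcoxon signed-rank machinery over per-family mean
coverages (the age x location battery of 108 contrasts across three
libraries), the multiple-testing correction 1-(1-p)^n (a Sidak-form
familywise adjustment), Mann-Whitney comparisons across gene-expression
groups, log2 sense/antisense strand-bias ratios from uniquely mapping
reads, the young-versus-old proximal-fraction comparison, and strand- and
repeat-resolved TSS metaprofiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .locus_grouping import AGE_GROUPS

log = logging.getLogger(__name__)

LOCATION_PAIRS = (
    ("genic", "proximal"),
    ("proximal", "distal"),
    ("genic", "distal"),
)


@dataclass
class PairedTestResult:
    rte_type: str
    age_group: str
    group_a: str
    group_b: str
    library: str
    n_families: int
    statistic: float
    p_raw: float
    p_corrected: float
    direction: str  # greater/less/none: sign of median(a - b)
    significance_tier: str  # ns / '0.05' / '0.001'
    underpowered: bool


def wilcoxon_signed_rank_paired(
    a, b=None, min_pairs: int = 5
) -> tuple[float, float, int, bool]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Accepts paired arrays (a, b) or a single array of differences.  NaN
    pairs and zero differences are dropped (classical convention); the
    exact null is used for n <= 25 without ties, the tie-corrected normal
    approximation otherwise.  Returns (statistic, p, n_used, underpowered)
    where underpowered flags fewer than ``min_pairs`` informative pairs.
    """
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 0, True
    exact = n <= 25 and len(np.unique(np.abs(d))) == n
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        alternative="two-sided",
        correction=False,
        method="exact" if exact else "approx",
    )
    return float(res.statistic), float(res.pvalue), n, n < min_pairs


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (exact for small tie-free samples)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if len(a) < 3 or len(b) < 3:
        log.warning("Mann-Whitney with group size < 3 is underpowered")
    pooled = np.concatenate([a, b])
    exact = len(a) <= 20 and len(b) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def correct_p(p_raw: float, n: int) -> float:
    """Familywise correction 1 - (1-p)^n, computed stably for small p."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(-math.expm1(n * math.log1p(-p_raw))) if p_raw < 1.0 else 1.0


def _tier(p_corrected: float) -> str:
    if p_corrected < 0.001:
        return "0.001"
    if p_corrected < 0.05:
        return "0.05"
    return "ns"


def figure5_battery(
    nine_means: pd.DataFrame,
    n_correction: int | None = None,
    min_families: int = 5,
) -> pd.DataFrame:
    """Run the full age x location-pair x RTE-type x library battery.

    ``nine_means`` is long-form with columns family, rte_type, library,
    age_group, location_group, mean_coverage (NaN for empty cells).  For
    each contrast the per-family pair of cell means feeds a paired
    Wilcoxon; families missing either cell drop out of that contrast.  The
    correction n defaults to the number of contrasts actually run (108
    when everything is runnable).  Direction is the sign of the median
    paired difference; tiers follow the corrected p (0.05 / 0.001).
    """
    required = {"family", "rte_type", "library", "age_group", "location_group", "mean_coverage"}
    missing = required - set(nine_means.columns)
    if missing:
        raise ValueError(f"nine_means missing columns {sorted(missing)}")
    rows = []
    rte_types = sorted(nine_means["rte_type"].unique())
    libraries = sorted(nine_means["library"].unique())
    cells = (
        nine_means.set_index(
            ["library", "rte_type", "age_group", "location_group", "family"]
        )["mean_coverage"]
        .sort_index()
    )
    for library in libraries:
        for rte_type in rte_types:
            for age in AGE_GROUPS:
                for loc_a, loc_b in LOCATION_PAIRS:
                    try:
                        va = cells.loc[(library, rte_type, age, loc_a)]
                        vb = cells.loc[(library, rte_type, age, loc_b)]
                    except KeyError:
                        va = pd.Series(dtype=float)
                        vb = pd.Series(dtype=float)
                    paired = pd.DataFrame({"a": va, "b": vb}).dropna()
                    stat, p, n_used, under = wilcoxon_signed_rank_paired(
                        paired["a"].to_numpy(), paired["b"].to_numpy(), min_pairs=min_families
                    )
                    diffs = paired["a"] - paired["b"]
                    med = float(diffs.median()) if len(diffs) else 0.0
                    direction = "greater" if med > 0 else ("less" if med < 0 else "none")
                    rows.append(
                        {
                            "library": library,
                            "rte_type": rte_type,
                            "age_group": age,
                            "group_a": loc_a,
                            "group_b": loc_b,
                            "n_families": n_used,
                            "statistic": stat,
                            "p_raw": p,
                            "direction": direction,
                            "underpowered": under,
                        }
                    )
    out = pd.DataFrame(rows)
    n_corr = n_correction if n_correction is not None else len(out)
    out["p_corrected"] = [correct_p(p, n_corr) for p in out["p_raw"]]
    out["n_correction"] = n_corr
    out["significance_tier"] = [
        "ns" if under else _tier(pc)
        for pc, under in zip(out["p_corrected"], out["underpowered"])
    ]
    return out


def strand_bias(unique_sense: float, unique_antisense: float, pseudocount: float = 0.5) -> float:
    """log2((sense + c) / (antisense + c)) with a Haldane-Anscombe pseudocount."""
    if unique_sense < 0 or unique_antisense < 0:
        raise ValueError("counts must be nonnegative")
    return float(np.log2((unique_sense + pseudocount) / (unique_antisense + pseudocount)))


def strand_bias_table(
    cov: pd.DataFrame,
    loci_df: pd.DataFrame,
    relative_strand: pd.Series,
    library: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per (rte_type, forward/reverse/nongenic) log2 unique sense/antisense.

    Unique counts are summed over loci first, then the ratio is taken.
    """
    df = pd.DataFrame(
        {
            "rte_type": loci_df["rte_type"],
            "category": relative_strand.reindex(loci_df.index).fillna("nongenic"),
            "unique_sense": cov["unique_sense"],
            "unique_antisense": cov["unique_antisense"],
        }
    )
    agg = df.groupby(["rte_type", "category"], sort=True)[
        ["unique_sense", "unique_antisense"]
    ].sum()
    rows = []
    for (rte_type, category), row in agg.iterrows():
        rows.append(
            {
                "library": library,
                "rte_type": rte_type,
                "category": category,
                "unique_sense": int(row["unique_sense"]),
                "unique_antisense": int(row["unique_antisense"]),
                "log2_ratio": strand_bias(
                    row["unique_sense"], row["unique_antisense"], pseudocount
                ),
            }
        )
    return pd.DataFrame(rows)


def proximal_fraction_comparison(
    assignments: pd.DataFrame, denominator: str = "all"
) -> tuple[float, float, int]:
    """Is the proximal fraction higher among young than among old loci?

    Per family: the fraction of young-group loci that are proximal versus
    the same for the old group (``denominator='all'`` divides by the age
    group size; ``'nongenic'`` divides by its non-genic loci only).
    Returns (fraction of families with young > old, paired Wilcoxon p,
    number of families compared).  Tied families leave the numerator and
    the signed-rank test (zero difference) but stay in the denominator.
    """
    if denominator not in ("all", "nongenic"):
        raise ValueError("denominator must be 'all' or 'nongenic'")
    young_frac = {}
    old_frac = {}
    for family, grp in assignments.groupby("family", sort=True):
        fr = {}
        for age in ("young", "old"):
            sub = grp[grp["age_group"] == age]
            if denominator == "nongenic":
                sub_nong = sub[sub["location_group"] != "genic"]
                fr[age] = (
                    (sub_nong["location_group"] == "proximal").mean()
                    if len(sub_nong)
                    else np.nan
                )
            else:
                fr[age] = (
                    (sub["location_group"] == "proximal").mean() if len(sub) else np.nan
                )
        if not (np.isnan(fr["young"]) or np.isnan(fr["old"])):
            young_frac[family] = fr["young"]
            old_frac[family] = fr["old"]
    families = sorted(young_frac)
    if len(families) < 3:
        raise ValueError("need at least 3 families with young and old loci")
    y = np.array([young_frac[f] for f in families])
    o = np.array([old_frac[f] for f in families])
    fraction_higher = float((y > o).sum() / len(families))
    _, p, _, _ = wilcoxon_signed_rank_paired(y, o)
    return fraction_higher, p, len(families)


def tss_profile(
    mappings: pd.DataFrame,
    tss_records,
    loci_df: pd.DataFrame,
    half_width: int = 2000,
    bin_size: int = 10,
) -> pd.DataFrame:
    """Strand-specific weighted read density around TSS.

    Offsets are gene-orientation-normalized (positive = downstream of the
    TSS in transcription direction) and binned; the mapping strand is taken
    relative to the gene strand (sense = same).  Mappings contained in an
    RTE locus are tracked separately from the rest.  Each mapping
    contributes 1/multiplicity to every TSS window that covers it.
    """
    if half_width % bin_size != 0:
        raise ValueError("half_width must be a multiple of bin_size")
    from .coverage_engine import LocusIndex

    n_bins = 2 * half_width // bin_size
    edges_left = -half_width
    tracks = {
        (rel, rte): np.zeros(n_bins)
        for rel in ("sense", "antisense")
        for rte in ("rte", "nonrte")
    }
    index = LocusIndex(loci_df) if len(loci_df) else None
    by_chrom: dict[str, list] = {}
    for r in tss_records:
        by_chrom.setdefault(r.chrom, []).append(r)
    in_rte_cache: dict[int, bool] = {}
    for chrom, grp in mappings.groupby("chrom", sort=True):
        recs = by_chrom.get(chrom)
        if not recs:
            continue
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        strands = grp["strand"].to_numpy()
        weights = grp["weight"].to_numpy()
        rows = grp.index.to_numpy()
        for rec in recs:
            lo = int(np.searchsorted(starts, rec.position - half_width))
            hi = int(np.searchsorted(starts, rec.position + half_width))
            for j in range(lo, hi):
                pos = int(starts[j])
                offset = pos - rec.position if rec.strand == "+" else rec.position - pos
                if not (-half_width <= offset < half_width):
                    continue
                key = int(rows[j])
                in_rte = in_rte_cache.get(key)
                if in_rte is None:
                    in_rte = bool(index and index.containing(chrom, pos, int(ends[j])))
                    in_rte_cache[key] = in_rte
                rel = "sense" if strands[j] == rec.strand else "antisense"
                b = (offset - edges_left) // bin_size
                tracks[(rel, "rte" if in_rte else "nonrte")][b] += weights[j]
    offsets = np.arange(-half_width, half_width, bin_size)
    return pd.DataFrame(
        {
            "offset": offsets,
            "sense_rte": tracks[("sense", "rte")],
            "sense_nonrte": tracks[("sense", "nonrte")],
            "antisense_rte": tracks[("antisense", "rte")],
            "antisense_nonrte": tracks[("antisense", "nonrte")],
        }
    )
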