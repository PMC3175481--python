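"""End-to-end pipeline: filter -> map -> coverage -> group -> stats.

``run_all`` drives a full analysis from a :class:`~pirte.config.RunConfig`
— simulating inputs or consuming files on disk — and writes the
figure-equivalent TSV bundle.  ``analyze`` is the in-memory core and is
what the tests exercise.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .annotation_io import loci_frame, tss_from_genes
from .config import AnalysisConfig, RunConfig
from .coverage_engine import (
    assign_reads_to_loci,
    coverage_table,
    family_summary,
    genic_coverage_fraction,
    library_correlation,
    mappings_frame,
)
from .locus_grouping import (
    all_nine_group_means,
    expression_groups,
    gene_window_coverage,
    group_assignments,
    intronic_composition,
    select_isolated_genes,
)
from .read_processing import (
    GenomeIndex,
    filter_reads,
    length_histogram,
    map_reads,
    remove_tss_proximal,
)
from .stats_report import (
    figure5_battery,
    mann_whitney_u,
    proximal_fraction_comparison,
    strand_bias_table,
    tss_profile,
)

log = logging.getLogger(__name__)


@dataclass
class LibraryResult:
    name: str
    filter_report: object
    library_size: int
    n_unmapped: int
    mapping_sets: list
    mappings: pd.DataFrame
    coverage: pd.DataFrame  # indexed by locus_id
    length_hist: dict[int, int]


@dataclass
class AnalysisResult:
    loci_df: pd.DataFrame
    assignments: pd.DataFrame
    libraries: dict[str, LibraryResult]
    nine_means: pd.DataFrame
    battery: pd.DataFrame
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def process_library(
    index: GenomeIndex, name: str, reads, analysis: AnalysisConfig, loci_df, tss_records
) -> LibraryResult:
    """Filter, map and summarize one read library.

    The library size used for normalization is the number of reads with at
    least one perfect match after all filters (including, when enabled,
    TSS-proximal read removal).
    """
    filtered, report = filter_reads(
        reads, complexity_threshold=analysis.complexity_threshold, window=analysis.complexity_window
    )
    mapping_sets, unmapped = map_reads(index, filtered)
    if analysis.remove_tss_reads:
        mapping_sets = remove_tss_proximal(
            mapping_sets, tss_records, radius=analysis.tss_radius, mode=analysis.tss_mode
        )
    library_size = len(mapping_sets)
    mdf = mappings_frame(mapping_sets)
    cov = coverage_table(
        loci_df, mdf, max(library_size, 1), library=name, mode=analysis.overlap_mode
    ).set_index("locus_id", drop=False).rename_axis(None)
    return LibraryResult(
        name=name,
        filter_report=report,
        library_size=library_size,
        n_unmapped=len(unmapped),
        mapping_sets=mapping_sets,
        mappings=mdf,
        coverage=cov,
        length_hist=length_histogram(filtered),
    )


def _eligibility(mdf: pd.DataFrame, assign: pd.DataFrame, loci_df: pd.DataFrame):
    """Per-read exclusivity scopes from an existing assignment table."""
    sf_map = loci_df["superfamily"].to_dict()
    fam_map = loci_df["family"].to_dict()
    row_sf: dict[int, set] = defaultdict(set)
    row_fam: dict[int, set] = defaultdict(set)
    for r, l in zip(assign["mapping_row"].to_numpy(), assign["locus_id"].to_numpy()):
        row_sf[r].add(sf_map[l])
        row_fam[r].add(fam_map[l])
    elig: dict[str, tuple[set, set]] = {}
    for read_id, rows in mdf.groupby("read_id").indices.items():
        sf: set | None = None
        fam: set | None = None
        for r in rows:
            s = row_sf.get(r, set())
            f = row_fam.get(r, set())
            sf = set(s) if sf is None else (sf & s)
            fam = set(f) if fam is None else (fam & f)
            if not sf and not fam:
                break
        elig[read_id] = (sf or set(), fam or set())
    return elig


def _exclusive_raw(
    loci_df: pd.DataFrame, mdf: pd.DataFrame, assign: pd.DataFrame, elig, scope: str
) -> pd.Series:
    scope_map = (loci_df["superfamily"] if scope == "superfamily" else loci_df["family"]).to_dict()
    si = 0 if scope == "superfamily" else 1
    read_ids = mdf["read_id"].to_numpy()
    weights = mdf["weight"].to_numpy()
    sums: dict = defaultdict(float)
    for r, l in zip(assign["mapping_row"].to_numpy(), assign["locus_id"].to_numpy()):
        if scope_map[l] in elig[read_ids[r]][si]:
            sums[l] += weights[r]
    return pd.Series(sums, dtype=float).reindex(loci_df.index, fill_value=0.0)


def analyze(
    genome: dict[str, str],
    loci,
    genes,
    expression: dict[str, float] | None,
    reads_by_library: dict[str, list],
    analysis: AnalysisConfig | None = None,
    full: bool = True,
    allow_skip: bool = True,
) -> AnalysisResult:
    """Run the analysis on in-memory inputs.

    ``full=False`` computes only what the age/location test battery needs
    (coverage, grouping, nine-group means, battery, strand bias) and skips
    the exclusivity, gene-expression and TSS-profile reports.
    """
    analysis = analysis or AnalysisConfig()
    loci_df = loci_frame(loci)
    tss_records = tss_from_genes(genes)
    index = GenomeIndex(genome, k=analysis.index_k)

    libraries: dict[str, LibraryResult] = {}
    for name, reads in reads_by_library.items():
        libraries[name] = process_library(index, name, reads, analysis, loci_df, tss_records)

    assignments = group_assignments(loci_df, genes, min_family_size=3)
    nine_frames = []
    for name, lib in libraries.items():
        nm = all_nine_group_means(lib.coverage["coverage"], assignments)
        nm["library"] = name
        nine_frames.append(nm)
    nine_means = pd.concat(nine_frames, ignore_index=True)
    battery = figure5_battery(
        nine_means,
        n_correction=analysis.n_correction,
        min_families=analysis.min_families_for_test,
    )

    result = AnalysisResult(
        loci_df=loci_df,
        assignments=assignments,
        libraries=libraries,
        nine_means=nine_means,
        battery=battery,
    )
    tables = result.tables
    tables["fig5_battery"] = battery

    # Strand bias (unique-read sense/antisense by gene-relative orientation).
    bias_frames = [
        strand_bias_table(
            lib.coverage,
            loci_df,
            assignments["gene_relative_strand"],
            library=name,
            pseudocount=analysis.pseudocount,
        )
        for name, lib in libraries.items()
    ]
    tables["fig7_strand_bias"] = pd.concat(bias_frames, ignore_index=True)

    # Young-vs-old proximal fraction across families.
    try:
        frac, p, n_fam = proximal_fraction_comparison(assignments)
        tables["proximal_fraction"] = pd.DataFrame(
            [{"fraction_families_young_higher": frac, "wilcoxon_p": p, "n_families": n_fam}]
        )
    except ValueError as exc:
        result.notes.append(f"proximal_fraction skipped: {exc}")

    # Age-group mean coverage per type (tertile trend summary).
    age_rows = []
    for name, lib in libraries.items():
        df = assignments[["rte_type", "age_group"]].copy()
        df["coverage"] = lib.coverage["coverage"].loc[df.index]
        g = df.groupby(["rte_type", "age_group"], sort=True)["coverage"].mean().reset_index()
        g["library"] = name
        age_rows.append(g)
    tables["age_group_means"] = pd.concat(age_rows, ignore_index=True)

    # Family summaries (age vs coverage; library correlations).
    summaries = []
    for name, lib in libraries.items():
        fs = family_summary(lib.coverage, loci_df, min_loci=analysis.min_loci_per_family)
        fs["library"] = name
        summaries.append(fs)
    fam_sum = pd.concat(summaries, ignore_index=True)
    tables["fig2_age_vs_coverage"] = fam_sum

    corr_rows = []
    names = sorted(libraries)
    for i, la in enumerate(names):
        for lb in names[i + 1 :]:
            ma = fam_sum[fam_sum["library"] == la].set_index("family")["median_coverage"]
            mb = fam_sum[fam_sum["library"] == lb].set_index("family")["median_coverage"]
            if len(ma.index.intersection(mb.index)) >= 3:
                corr_rows.append(
                    {
                        "library_a": la,
                        "library_b": lb,
                        "spearman_rho": library_correlation(ma, mb),
                        "n_families": len(ma.index.intersection(mb.index)),
                    }
                )
    tables["figS1_correlations"] = pd.DataFrame(
        corr_rows, columns=["library_a", "library_b", "spearman_rho", "n_families"]
    )

    # Genic coverage fractions (all reads).
    genic_rows = []
    for name, lib in libraries.items():
        for rte_type in sorted(loci_df["rte_type"].unique()):
            cov_frac, locus_frac = genic_coverage_fraction(
                lib.coverage, assignments["location_group"], loci_df, rte_type
            )
            genic_rows.append(
                {
                    "library": name,
                    "rte_type": rte_type,
                    "read_scope": "all",
                    "coverage_fraction": np.nan if cov_frac is None else cov_frac,
                    "locus_fraction": locus_frac,
                }
            )
    fig6 = pd.DataFrame(genic_rows)

    # Read-length histograms.
    len_rows = []
    for name, lib in libraries.items():
        for length, count in lib.length_hist.items():
            len_rows.append({"library": name, "read_length": length, "count": count})
    tables["figS4_lengths"] = pd.DataFrame(len_rows, columns=["library", "read_length", "count"])

    # Intronic (genic) RTE composition.
    comp = intronic_composition(loci_df, assignments["location_group"])
    tables["figS5_composition"] = comp.reset_index().rename(columns={"index": "rte_type"})

    # Filter reports.
    tables["filter_report"] = pd.DataFrame(
        [
            {
                "library": name,
                "n_raw": lib.filter_report.n_raw,
                "n_ambiguous_removed": lib.filter_report.n_ambiguous_removed,
                "n_low_complexity_removed": lib.filter_report.n_low_complexity_removed,
                "fraction_filtered": lib.filter_report.fraction_filtered,
                "n_mapped": lib.library_size,
                "n_unmapped": lib.n_unmapped,
            }
            for name, lib in libraries.items()
        ]
    )

    if full:
        # Exclusivity-restricted coverage (fig1 / fig6 family columns).
        fig1_rows = []
        excl_fracs = []
        for name, lib in libraries.items():
            assign = assign_reads_to_loci(lib.mappings, loci_df, mode=analysis.overlap_mode)
            elig = _eligibility(lib.mappings, assign, loci_df)
            raw_sf = _exclusive_raw(loci_df, lib.mappings, assign, elig, "superfamily")
            raw_fam = _exclusive_raw(loci_df, lib.mappings, assign, elig, "family")
            denom = (loci_df["length"] / 1000.0) * (max(lib.library_size, 1) / 1e6)
            cov_sf = raw_sf / denom
            cov_fam = raw_fam / denom
            merged = pd.DataFrame(
                {
                    "family": loci_df["family"],
                    "superfamily": loci_df["superfamily"],
                    "rte_type": loci_df["rte_type"],
                    "all": lib.coverage["coverage"],
                    "superfamily_exclusive": cov_sf,
                    "family_exclusive": cov_fam,
                }
            )
            for (family, superfam, rte_type), grp in merged.groupby(
                ["family", "superfamily", "rte_type"], sort=True
            ):
                if len(grp) < analysis.min_loci_per_family:
                    continue
                fig1_rows.append(
                    {
                        "library": name,
                        "family": family,
                        "superfamily": superfam,
                        "rte_type": rte_type,
                        "n_loci": len(grp),
                        "median_all": float(grp["all"].median()),
                        "median_superfamily_exclusive": float(
                            grp["superfamily_exclusive"].median()
                        ),
                        "median_family_exclusive": float(grp["family_exclusive"].median()),
                    }
                )
            # family-exclusive genic fraction
            for rte_type in sorted(loci_df["rte_type"].unique()):
                ids = loci_df.index[loci_df["rte_type"] == rte_type]
                total = float(raw_fam.loc[ids].sum())
                genic_ids = [
                    i
                    for i in ids
                    if assignments["location_group"].get(i) == "genic"
                ]
                excl_fracs.append(
                    {
                        "library": name,
                        "rte_type": rte_type,
                        "read_scope": "family_exclusive",
                        "coverage_fraction": (
                            float(raw_fam.loc[genic_ids].sum()) / total if total > 0 else np.nan
                        ),
                        "locus_fraction": len(genic_ids) / len(ids) if len(ids) else np.nan,
                    }
                )
        tables["fig1_family_medians"] = pd.DataFrame(
            fig1_rows,
            columns=[
                "library", "family", "superfamily", "rte_type", "n_loci",
                "median_all", "median_superfamily_exclusive", "median_family_exclusive",
            ],
        )
        fig6 = pd.concat([fig6, pd.DataFrame(excl_fracs)], ignore_index=True)

        # Expression groups and gene-window coverage.
        if expression:
            for_genes = [g for g in genes if g.expression is not None]
            isolated = select_isolated_genes(for_genes, min_gap=analysis.isolation_gap)
            if len(isolated) >= 8:
                groups = expression_groups(isolated)
                chrom_lengths = {c: len(s) for c, s in genome.items()}
                fig3_rows = []
                test_rows = []
                for name, lib in libraries.items():
                    per_gene = []
                    for g in isolated:
                        per_gene.extend(
                            gene_window_coverage(
                                g,
                                loci_df,
                                lib.coverage["raw_weighted_count"],
                                max(lib.library_size, 1),
                                flank=analysis.gene_flank,
                                expression_group=groups[g.gene_id],
                                chrom_length=chrom_lengths.get(g.chrom),
                            )
                        )
                    gw = pd.DataFrame(
                        [
                            {
                                "gene_id": r.gene_id,
                                "expression_group": r.expression_group,
                                "rte_type": r.rte_type,
                                "normalized_coverage": r.normalized_coverage,
                            }
                            for r in per_gene
                            if r.normalized_coverage is not None
                        ]
                    )
                    if gw.empty:
                        continue
                    for (rte_type, grp_name), grp in gw.groupby(
                        ["rte_type", "expression_group"], sort=True
                    ):
                        c = grp["normalized_coverage"].to_numpy()
                        fig3_rows.append(
                            {
                                "library": name,
                                "rte_type": rte_type,
                                "expression_group": grp_name,
                                "n_genes": len(c),
                                "median_coverage": float(np.median(c)),
                                "p25": float(np.percentile(c, 25)),
                                "p75": float(np.percentile(c, 75)),
                            }
                        )
                    for rte_type, grp in gw.groupby("rte_type", sort=True):
                        hi = grp[grp["expression_group"] == "high"]["normalized_coverage"]
                        lo = grp[grp["expression_group"] == "low"]["normalized_coverage"]
                        md = grp[grp["expression_group"] == "medium"]["normalized_coverage"]
                        for other_name, other in (("low", lo), ("medium", md)):
                            if len(hi) >= 3 and len(other) >= 3:
                                u, p = mann_whitney_u(hi, other)
                                test_rows.append(
                                    {
                                        "library": name,
                                        "rte_type": rte_type,
                                        "contrast": f"high_vs_{other_name}",
                                        "U": u,
                                        "p_two_sided": p,
                                    }
                                )
                tables["fig3_expression_groups"] = pd.DataFrame(fig3_rows)
                tables["fig3_tests"] = pd.DataFrame(test_rows)
            else:
                result.notes.append("fig3 skipped: fewer than 8 isolated genes")
        elif allow_skip:
            result.notes.append("fig3 skipped: no expression table")
        else:
            raise ValueError("expression table required (fig3) but missing")

        # TSS metaprofiles.
        prof_frames = []
        for name, lib in libraries.items():
            prof = tss_profile(
                lib.mappings,
                tss_records,
                loci_df,
                half_width=analysis.tss_profile_half_width,
                bin_size=analysis.tss_profile_bin,
            )
            prof.insert(0, "library", name)
            prof_frames.append(prof)
        tables["figS3_tss_profile"] = pd.concat(prof_frames, ignore_index=True)

    tables["fig6_genic_fractions"] = fig6
    return result


def write_tables(result: AnalysisResult, outdir, run_config: RunConfig | None = None, seed=None) -> dict[str, str]:
    """Write every result table as a headered TSV plus a run log.

    Output is deterministic: fixed column order, sorted rows where the
    producing step sorts, and a fixed float format.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name in sorted(result.tables):
        path = os.path.join(outdir, f"{name}.tsv")
        result.tables[name].to_csv(path, sep="\t", index=False, float_format="%.10g")
        paths[name] = path
    log_path = os.path.join(outdir, "run_log.txt")
    with open(log_path, "w") as fh:
        fh.write(f"pirte {__version__}\n")
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        if seed is not None:
            fh.write(f"seed {seed}\n")
        if run_config is not None:
            fh.write(f"analysis {dataclasses.asdict(run_config.analysis)}\n")
            fh.write(f"sim_seed {run_config.sim.seed}\n")
        for name, lib in sorted(result.libraries.items()):
            fh.write(
                f"library {name}: raw={lib.filter_report.n_raw} "
                f"mapped={lib.library_size} unmapped={lib.n_unmapped} "
                f"filtered_fraction={lib.filter_report.fraction_filtered:.6g}\n"
            )
        for note in result.notes:
            fh.write(f"note: {note}\n")
    paths["run_log"] = log_path
    return paths


def run_all(
    run_config: RunConfig,
    outdir,
    seed: int | None = None,
    write_inputs_dir: str | None = "inputs",
    allow_skip: bool = True,
) -> dict[str, str]:
    """Simulate inputs per the config and run the full analysis.

    Returns a manifest of written files.  ``seed`` overrides the config's
    simulation seed.
    """
    from .synthetic_data import simulate, write_inputs

    sim_cfg = run_config.sim
    if seed is not None:
        sim_cfg = dataclasses.replace(sim_cfg, seed=seed)
    bundle, libraries = simulate(sim_cfg)
    paths = {}
    if write_inputs_dir is not None:
        paths.update(
            write_inputs(bundle, libraries, os.path.join(outdir, write_inputs_dir))
        )
    reads_by_library = {lib.name: lib.reads for lib in libraries}
    result = analyze(
        bundle.genome,
        bundle.loci,
        bundle.genes,
        bundle.expression,
        reads_by_library,
        run_config.analysis,
        full=True,
        allow_skip=allow_skip,
    )
    paths.update(write_tables(result, outdir, run_config=run_config, seed=seed))
    return paths
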