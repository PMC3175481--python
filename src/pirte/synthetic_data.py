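"""Synthetic genomes, retrotransposon annotations and small-RNA libraries.

The generator emulates the structure the analysis assumes: several
retrotransposon (RTE) families per type whose copies are the family
consensus mutated at a per-copy rate (the recorded millidivergence is the
*realized* substitution count per 1000 bp, so annotated age is exact);
age-dependent and location-dependent read generation; and stage-dependent
strand coupling of genic reads to the host gene's orientation.  Low-
divergence copies of a family are near-identical, which produces the
multi-mapping reads the weighting scheme exists for.

Everything is driven by a single integer seed through
``numpy.random.SeedSequence`` spawning, so a fixed seed fixes every output
byte.
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_left, insort
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import GeneModel, RteLocus
from .config import ConfigError, FamilySpec, LibrarySpec, SimConfig
from .read_processing import ReadRecord, revcomp

PLACEMENTS = ("genic", "proximal", "distal")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(RuntimeError):
    pass


@dataclass
class GenomeBundle:
    """Everything :func:`plant_genome` knows about one synthetic genome."""

    genome: dict[str, str]
    loci: list[RteLocus]
    genes: list[GeneModel]
    expression: dict[str, float]
    truth_loci: pd.DataFrame  # locus_id, placement, host_gene, gene_distance, millidiv


@dataclass
class SimulatedLibrary:
    name: str
    reads: list[ReadRecord]
    truth_reads: pd.DataFrame  # read_id, locus_id, chrom, start, end, strand, placement


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def build_family_panel(config: SimConfig, rng: np.random.Generator) -> list[tuple[FamilySpec, str]]:
    """Draw one random consensus sequence per family.

    Duplicate family names are a configuration error; a fixed seed yields
    identical consensi on every run.
    """
    config.validate()
    panel = []
    for fam in config.families:
        consensus = _random_sequence(rng, fam.consensus_length).tobytes().decode("ascii")
        panel.append((fam, consensus))
    return panel


def _mutate_copy(consensus: np.ndarray, millidiv_target: float, rng: np.random.Generator):
    """Substitute exactly round(millidiv/1000 * L) positions of the consensus.

    Returns (sequence, realized millidiv rounded to one decimal).
    """
    L = len(consensus)
    n_sub = int(round(millidiv_target / 1000.0 * L))
    n_sub = min(n_sub, L)
    seq = consensus.copy()
    if n_sub:
        positions = rng.choice(L, size=n_sub, replace=False)
        shifts = rng.integers(1, 4, size=n_sub).astype(np.uint8)
        idx = np.searchsorted(_BASES, seq[positions])
        seq[positions] = _BASES[(idx + shifts) % 4]
    millidiv = round(n_sub * 10000.0 / L) / 10.0
    return seq, millidiv


class _Occupancy:
    """Per-chromosome interval bookkeeping to keep planted features disjoint."""

    def __init__(self):
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def is_free(self, chrom: str, start: int, end: int) -> bool:
        iv = self._by_chrom.get(chrom, [])
        i = bisect_left(iv, (start, end))
        if i < len(iv) and iv[i][0] < end:
            return False
        if i > 0 and iv[i - 1][1] > start:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self._by_chrom.setdefault(chrom, []), (start, end))


def _layout_genes(config: SimConfig, rng: np.random.Generator, chrom_names, chrom_len):
    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    gene_len = config.gene_length
    need = config.chrom_lead + max(per_chrom) * (gene_len + config.gene_spacing)
    if need + config.distal_floor + 50_000 > chrom_len:
        raise ConfigError(
            f"genome too short: need >= {need + config.distal_floor + 50_000} bp per "
            f"chromosome, have {chrom_len}"
        )
    gid = 0
    for ci, chrom in enumerate(chrom_names):
        for j in range(per_chrom[ci]):
            start = config.chrom_lead + j * (gene_len + config.gene_spacing)
            end = start + gene_len
            strand = "+" if rng.random() < 0.5 else "-"
            exon_starts = tuple(
                start + k * (config.exon_length + config.intron_length)
                for k in range(config.exons_per_gene)
            )
            exon_ends = tuple(s + config.exon_length for s in exon_starts)
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    tss=start if strand == "+" else end - 1,
                    exon_starts=exon_starts,
                    exon_ends=exon_ends,
                )
            )
    return genes


def _introns(gene: GeneModel) -> list[tuple[int, int]]:
    return [
        (e, s)
        for e, s in zip(gene.exon_ends[:-1], gene.exon_starts[1:])
        if s - e > 0
    ]


def _placement_weights(fam: FamilySpec, u: float, bias: float) -> np.ndarray:
    """Placement distribution for a copy with age fraction ``u`` in [0, 1].

    ``bias`` tilts young copies (u -> 0) towards the proximal band and old
    copies away from it, leaving the genic probability untouched.
    """
    g, p, d = fam.placement_probs
    p = max(p * (1.0 + bias * (1.0 - 2.0 * u)), 0.0)
    d = max(d * (1.0 + bias * (2.0 * u - 1.0)), 0.0)
    w = np.array([g, p, d], dtype=float)
    total = w.sum()
    if total <= 0:
        raise SimulationError(f"family {fam.name}: degenerate placement weights")
    return w / total


def plant_genome(
    config: SimConfig, panel, rng: np.random.Generator
) -> GenomeBundle:
    """Realize the genome: background sequence, genes, and RTE copies.

    Copies are placed in introns (genic), within the proximal band of a
    gene edge, or in the gene-free desert at the chromosome tail (distal),
    according to each family's (possibly age-biased) placement
    distribution.  Planted intervals never overlap.  Failure to place a
    copy after bounded retries raises a :class:`SimulationError` naming the
    family.
    """
    config.validate()
    chrom_len = config.genome_length // config.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genes = _layout_genes(config, rng, chrom_names, chrom_len)
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    desert: dict[str, tuple[int, int]] = {}
    for chrom in chrom_names:
        glist = genes_by_chrom.get(chrom, [])
        last_end = max((g.end for g in glist), default=0)
        desert[chrom] = (last_end + config.distal_floor, chrom_len - 100)

    occupied = _Occupancy()
    chrom_arrays = {c: _random_sequence(rng, chrom_len) for c in chrom_names}

    band_lo, band_hi = config.proximal_band
    loci: list[RteLocus] = []
    truth_rows = []
    for fam, consensus in panel:
        cons = np.frombuffer(consensus.encode("ascii"), dtype=np.uint8).copy()
        lo, hi = fam.millidiv_range
        for copy_idx in range(fam.n_copies):
            m_target = float(rng.uniform(lo, hi))
            u = 0.5 if hi == lo else (m_target - lo) / (hi - lo)
            weights = _placement_weights(fam, u, config.young_proximal_bias)
            placement = PLACEMENTS[int(rng.choice(3, p=weights))]
            seq, millidiv = _mutate_copy(cons, m_target, rng)
            L = len(seq)
            placed = None
            host_gene = None
            for _attempt in range(500):
                if placement == "genic":
                    if not genes:
                        raise SimulationError(
                            f"family {fam.name}: genic placement requested with no genes"
                        )
                    gene = genes[int(rng.integers(0, len(genes)))]
                    introns = [iv for iv in _introns(gene) if iv[1] - iv[0] >= L + 10]
                    if not introns:
                        continue
                    ivs, ive = introns[int(rng.integers(0, len(introns)))]
                    start = int(rng.integers(ivs + 5, ive - L - 4))
                    chrom = gene.chrom
                    host_gene = gene
                elif placement == "proximal":
                    gene = genes[int(rng.integers(0, len(genes)))]
                    side = int(rng.integers(0, 2))
                    dist = int(rng.integers(band_lo, band_hi - L))
                    if side == 0:
                        start = gene.start - dist - L
                    else:
                        start = gene.end + dist
                    chrom = gene.chrom
                    if start < 0 or start + L > chrom_len:
                        continue
                else:
                    chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
                    d0, d1 = desert[chrom]
                    if d1 - d0 < L + 2:
                        continue
                    start = int(rng.integers(d0, d1 - L))
                if occupied.is_free(chrom, start, start + L):
                    placed = (chrom, start)
                    break
            if placed is None:
                raise SimulationError(
                    f"family {fam.name}: could not place copy {copy_idx} "
                    f"({placement}) without overlap after 500 retries"
                )
            chrom, start = placed
            occupied.add(chrom, start, start + L)
            strand = "+" if rng.random() < 0.5 else "-"
            chrom_arrays[chrom][start : start + L] = (
                seq if strand == "+" else np.frombuffer(
                    revcomp(seq.tobytes().decode("ascii")).encode("ascii"), dtype=np.uint8
                )
            )
            locus_id = f"{fam.name}.{copy_idx + 1:04d}"
            loci.append(
                RteLocus(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=start,
                    end=start + L,
                    strand=strand,
                    family=fam.name,
                    superfamily=fam.superfamily,
                    rte_type=fam.rte_type,
                    millidiv=millidiv,
                )
            )
            mid = start + L // 2
            gdist = _distance_to_genes(mid, genes_by_chrom.get(chrom, []))
            truth_rows.append(
                {
                    "locus_id": locus_id,
                    "family": fam.name,
                    "rte_type": fam.rte_type,
                    "placement": placement,
                    "host_gene": host_gene.gene_id if host_gene is not None else "",
                    "host_gene_strand": host_gene.strand if host_gene is not None else "",
                    "gene_distance": gdist,
                    "millidiv": millidiv,
                    "strand": strand,
                }
            )

    mu, sigma = config.expression_lognormal_params
    expression = {
        g.gene_id: float(np.exp(rng.normal(mu, sigma))) for g in genes
    }
    genes = [
        GeneModel(
            gene_id=g.gene_id,
            chrom=g.chrom,
            start=g.start,
            end=g.end,
            strand=g.strand,
            tss=g.tss,
            exon_starts=g.exon_starts,
            exon_ends=g.exon_ends,
            expression=expression[g.gene_id],
        )
        for g in genes
    ]
    genome = {c: a.tobytes().decode("ascii") for c, a in chrom_arrays.items()}
    truth = pd.DataFrame(truth_rows).set_index("locus_id", drop=False).rename_axis(None)
    return GenomeBundle(genome=genome, loci=loci, genes=genes, expression=expression, truth_loci=truth)


def _distance_to_genes(mid: int, genes: list[GeneModel]) -> int:
    best = -1
    for g in genes:
        if g.start <= mid < g.end:
            return 0
        d = g.start - mid if mid < g.start else mid - (g.end - 1)
        if best < 0 or d < best:
            best = d
    return best


def expected_rate(spec: LibrarySpec, millidiv: float, placement: str) -> float:
    """Closed-form Poisson mean for one locus under a library profile."""
    factor = dict(zip(PLACEMENTS, spec.location_factors))[placement]
    return spec.base_rate * math.exp(-spec.age_decay * millidiv) * factor


def simulate_reads(
    genome: dict[str, str],
    loci,
    genes,
    spec: LibrarySpec,
    rng: np.random.Generator,
    truth_loci: pd.DataFrame | None = None,
    min_read_length: int = 16,
) -> SimulatedLibrary:
    """Draw a small-RNA library from planted loci.

    Per-locus counts are Poisson with the age/location-dependent mean;
    read starts are uniform within the locus and reads never extend past
    locus ends.  Genic reads are emitted from the host gene's strand with
    probability ``host_strand_coupling``; non-genic reads from the element
    strand with probability ``sense_fraction_nongenic``.  Every read is a
    literal genome substring (reverse-complemented for minus-strand
    origin).
    """
    spec.validate()
    if not loci:
        raise SimulationError("simulate_reads: no loci")
    if truth_loci is None:
        truth_loci = _derive_truth(loci, genes)
    lam = np.array(
        [
            expected_rate(
                spec,
                loc.millidiv,
                truth_loci.loc[loc.locus_id, "placement"],
            )
            for loc in loci
        ]
    )
    if not np.all(np.isfinite(lam)):
        raise SimulationError("non-finite read rate")
    if spec.n_reads is not None:
        total = lam.sum()
        if total > 0:
            lam = lam * (spec.n_reads / total)
    counts = rng.poisson(lam)
    lo_len, hi_len = spec.read_length_range
    reads: list[ReadRecord] = []
    rows = []
    skipped_short = 0
    serial = 0
    for loc, n in zip(loci, counts):
        if n == 0:
            continue
        if loc.length < min_read_length:
            skipped_short += 1
            continue
        placement = truth_loci.loc[loc.locus_id, "placement"]
        host_strand = truth_loci.loc[loc.locus_id, "host_gene_strand"]
        seq = genome[loc.chrom]
        for _ in range(int(n)):
            length = int(rng.integers(lo_len, hi_len + 1))
            if length > loc.length:
                length = loc.length  # truncated at locus ends
            start = loc.start + int(rng.integers(0, loc.length - length + 1))
            if placement == "genic" and host_strand:
                strand = host_strand if rng.random() < spec.host_strand_coupling else (
                    "-" if host_strand == "+" else "+"
                )
            else:
                strand = loc.strand if rng.random() < spec.sense_fraction_nongenic else (
                    "-" if loc.strand == "+" else "+"
                )
            serial += 1
            read_id = f"{spec.name}_{serial:07d}"
            fragment = seq[start : start + length]
            reads.append(ReadRecord(read_id, fragment if strand == "+" else revcomp(fragment)))
            rows.append(
                {
                    "read_id": read_id,
                    "locus_id": loc.locus_id,
                    "chrom": loc.chrom,
                    "start": start,
                    "end": start + length,
                    "strand": strand,
                    "placement": placement,
                }
            )
    if skipped_short:
        warnings.warn(
            f"library {spec.name}: skipped {skipped_short} locus/loci shorter than "
            f"the minimum read length"
        )
    truth = pd.DataFrame(
        rows, columns=["read_id", "locus_id", "chrom", "start", "end", "strand", "placement"]
    )
    return SimulatedLibrary(name=spec.name, reads=reads, truth_reads=truth)


def _derive_truth(loci, genes) -> pd.DataFrame:
    rows = []
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for loc in loci:
        mid = loc.midpoint
        host = next(
            (g for g in genes_by_chrom.get(loc.chrom, []) if g.start <= mid < g.end), None
        )
        rows.append(
            {
                "locus_id": loc.locus_id,
                "placement": "genic" if host else "distal",
                "host_gene": host.gene_id if host else "",
                "host_gene_strand": host.strand if host else "",
            }
        )
    return pd.DataFrame(rows).set_index("locus_id", drop=False).rename_axis(None)


def simulate(config: SimConfig) -> tuple[GenomeBundle, list[SimulatedLibrary]]:
    """End-to-end simulation from a config: genome, annotation, libraries."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    panel_ss, genome_ss, *lib_ss = ss.spawn(2 + len(config.libraries))
    panel = build_family_panel(config, np.random.default_rng(panel_ss))
    bundle = plant_genome(config, panel, np.random.default_rng(genome_ss))
    libraries = [
        simulate_reads(
            bundle.genome,
            bundle.loci,
            bundle.genes,
            spec,
            np.random.default_rng(s),
            truth_loci=bundle.truth_loci,
        )
        for spec, s in zip(config.libraries, lib_ss)
    ]
    return bundle, libraries


def write_inputs(bundle: GenomeBundle, libraries, outdir, rates: bool = True) -> dict[str, str]:
    """Write all standard-format pipeline inputs plus truth tables.

    Returns a manifest of logical name -> path.
    """
    import os

    from . import annotation_io as aio
    from .read_processing import write_fasta_reads

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    fa = os.path.join(outdir, "genome.fa")
    with open(fa, "w") as fh:
        for chrom in sorted(bundle.genome):
            fh.write(f">{chrom}\n")
            seq = bundle.genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genome"] = fa

    rm = os.path.join(outdir, "rte.out")
    aio.write_repeatmasker_out(bundle.loci, rm)
    paths["rmsk"] = rm

    bed = os.path.join(outdir, "genes.bed")
    aio.write_bed12_genes(bundle.genes, bed)
    paths["genes"] = bed

    expr = os.path.join(outdir, "expression.tsv")
    aio.write_expression(bundle.expression, expr)
    paths["expression"] = expr

    truth = os.path.join(outdir, "truth_loci.tsv")
    bundle.truth_loci.to_csv(truth, sep="\t", index=False)
    paths["truth_loci"] = truth

    for lib in libraries:
        rp = os.path.join(outdir, f"reads_{lib.name}.fa")
        write_fasta_reads(lib.reads, rp)
        paths[f"reads_{lib.name}"] = rp
        tp = os.path.join(outdir, f"truth_reads_{lib.name}.tsv")
        lib.truth_reads.to_csv(tp, sep="\t", index=False)
        paths[f"truth_reads_{lib.name}"] = tp
    return paths


def write_collapsed_fasta(reads, path) -> None:
    """Count-collapsed FASTA dialect: one record per distinct sequence,
    id formatted ``seqNNN_count``."""
    counts: dict[str, int] = {}
    for r in reads:
        counts[r.sequence] = counts.get(r.sequence, 0) + 1
    with open(path, "w") as fh:
        for i, (seq, n) in enumerate(sorted(counts.items()), start=1):
            fh.write(f">seq{i}_{n}\n{seq}\n")


# ---------------------------------------------------------------------------
# Stock configurations.  These encode the study conditions the test battery
# and the worked examples run under; sizes are desk-scale stand-ins for the
# genome-wide originals.
# ---------------------------------------------------------------------------

_AGE_DECAY = math.log(8.0) / 300.0  # 8-fold rate drop across the millidiv range


def _family_block(n_per_super: int, copies: int, millidiv=(0.0, 300.0), placement=(1 / 3, 1 / 3, 1 / 3)):
    fams = []
    blocks = [
        ("LINE", "L1", "L1Md_{i}", 300),
        ("LINE", "L2", "L2_{i}", 300),
        ("SINE", "Alu", "B1_{i}", 150),
        ("SINE", "B2", "B2_{i}", 150),
        ("LTRint", "ERVK", "IAP{i}-int", 280),
        ("LTRint", "ERVL", "ERVL{i}-int", 280),
        ("LTRter", "ERVK", "IAP{i}-LTR", 200),
        ("LTRter", "ERVL", "ERVL{i}-LTR", 200),
    ]
    for rte_type, superfamily, pattern, length in blocks:
        for i in range(1, n_per_super + 1):
            fams.append(
                FamilySpec(
                    name=pattern.format(i=i),
                    superfamily=superfamily,
                    rte_type=rte_type,
                    consensus_length=length,
                    n_copies=copies,
                    millidiv_range=millidiv,
                    placement_probs=placement,
                )
            )
    return fams


def _stage_libraries(
    base_rate=6.0,
    age_decay=_AGE_DECAY,
    early_factors=(2.0, 4.0, 1.0),
    late_factors=(4.0, 4.0, 1.0),
    early_coupling=0.5,
    late_coupling=0.9,
):
    return [
        LibrarySpec("miwi2_early", base_rate, age_decay, early_factors, early_coupling),
        LibrarySpec("mili_early", base_rate, age_decay, early_factors, early_coupling),
        LibrarySpec("mili_late", base_rate, age_decay, late_factors, late_coupling),
    ]


def default_config(seed: int = 0) -> SimConfig:
    """The standard fixture: 72 families (18 per RTE type), 81 copies each,
    three stage-profiled libraries, age-decaying and location-dependent
    rates, and a young-near-genes placement bias."""
    return SimConfig(
        genome_length=5_000_000,
        n_chromosomes=2,
        families=_family_block(9, 81),
        n_genes=48,
        libraries=_stage_libraries(),
        seed=seed,
        young_proximal_bias=0.7,
    )


def small_config(seed: int = 0) -> SimConfig:
    """A <= 1 Mb fixture for oracle-equivalence and determinism checks."""
    return SimConfig(
        genome_length=1_000_000,
        n_chromosomes=1,
        families=_family_block(1, 30),
        n_genes=10,
        libraries=_stage_libraries(),
        seed=seed,
        exon_length=250,
        intron_length=3_000,
        young_proximal_bias=0.7,
    )


def null_config(seed: int = 0) -> SimConfig:
    """No planted effects: flat location factors, no age decay, no bias."""
    flat = [
        LibrarySpec(name, base_rate=6.0, age_decay=0.0, location_factors=(1.0, 1.0, 1.0))
        for name in ("miwi2_early", "mili_early", "mili_late")
    ]
    return SimConfig(
        genome_length=1_300_000,
        n_chromosomes=1,
        families=_family_block(3, 24),
        n_genes=12,
        libraries=flat,
        seed=seed,
        exon_length=250,
        intron_length=3_500,
        young_proximal_bias=0.0,
    )


def stock_run_config(kind: str = "default", seed: int = 0):
    """RunConfig for a stock simulation with desk-scale analysis settings.

    The family-size floor for family-level summaries is scaled to the
    synthetic family sizes (30 instead of the genome-scale 1000).
    """
    from .config import AnalysisConfig, RunConfig

    factory = {
        "default": default_config,
        "small": small_config,
        "null": null_config,
        "strand": strand_config,
    }[kind]
    return RunConfig(sim=factory(seed), analysis=AnalysisConfig(min_loci_per_family=30))


def strand_config(seed: int = 0, late_coupling: float = 0.9) -> SimConfig:
    """High-divergence fixture for strand-bias recovery (unique-read rich)."""
    libs = [
        LibrarySpec("mili_early", base_rate=16.0, host_strand_coupling=0.5),
        LibrarySpec("mili_late", base_rate=16.0, host_strand_coupling=late_coupling),
    ]
    return SimConfig(
        genome_length=850_000,
        n_chromosomes=1,
        families=_family_block(
            1, 36, millidiv=(100.0, 400.0), placement=(0.5, 0.25, 0.25)
        ),
        n_genes=10,
        libraries=libs,
        seed=seed,
        exon_length=250,
        intron_length=3_000,
        young_proximal_bias=0.0,
    )
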