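"""Configuration objects for the simulator and the analysis pipeline.

All coordinates used internally are 0-based half-open.  The simulator is
parameterized by :class:`SimConfig` (genome layout, retrotransposon family
panel, small-RNA library profiles); analysis knobs live in
:class:`AnalysisConfig`.  Both serialize to/from a single YAML document so a
whole run is reproducible from one file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import yaml

RTE_TYPES = ("LINE", "SINE", "LTRint", "LTRter")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class FamilySpec:
    """One retrotransposon family: a consensus to be copied around the genome.

    ``millidiv_range`` bounds the per-copy divergence from the consensus in
    substitutions per 1000 bp (the age proxy); ``placement_probs`` is the
    (genic, proximal, distal) placement distribution for copies.
    """

    name: str
    superfamily: str
    rte_type: str
    consensus_length: int
    n_copies: int
    millidiv_range: tuple[float, float] = (0.0, 300.0)
    placement_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def validate(self) -> None:
        if self.rte_type not in RTE_TYPES:
            raise ConfigError(f"unknown rte_type {self.rte_type!r} for family {self.name}")
        if self.consensus_length < 50:
            raise ConfigError(f"family {self.name}: consensus_length must be >= 50")
        if self.n_copies < 1:
            raise ConfigError(f"family {self.name}: n_copies must be >= 1")
        lo, hi = self.millidiv_range
        if not (0 <= lo <= hi <= 1000):
            raise ConfigError(f"family {self.name}: millidiv_range must lie in [0, 1000]")
        probs = self.placement_probs
        if len(probs) != 3 or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(
                f"family {self.name}: placement_probs must be 3 nonnegative values summing to 1"
            )
        if self.rte_type == "LTRint" and not self.name.endswith("-int"):
            raise ConfigError(
                f"family {self.name}: LTRint family names must carry the '-int' suffix"
            )


@dataclass
class LibrarySpec:
    """Profile of one small-RNA library (a developmental stage / Piwi protein).

    Per-locus read counts are Poisson with mean
    ``base_rate * exp(-age_decay * millidiv) * location_factor(class)``.
    ``host_strand_coupling`` is the probability that a genic read is emitted
    from the host gene's transcribed strand (co-transcription); non-genic
    reads come from the element's own strand with probability
    ``sense_fraction_nongenic``.  If ``n_reads`` is set, ``base_rate`` is
    rescaled so the expected total read count equals it.
    """

    name: str
    base_rate: float = 6.0
    age_decay: float = 0.0
    location_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)
    host_strand_coupling: float = 0.5
    sense_fraction_nongenic: float = 0.5
    read_length_range: tuple[int, int] = (24, 30)
    n_reads: int | None = None

    def validate(self) -> None:
        for p in (self.host_strand_coupling, self.sense_fraction_nongenic):
            if not 0 <= p <= 1:
                raise ConfigError(f"library {self.name}: probabilities must lie in [0, 1]")
        lo, hi = self.read_length_range
        if not (16 <= lo <= hi <= 36):
            raise ConfigError(f"library {self.name}: read lengths must lie in [16, 36]")
        if self.base_rate < 0 or any(f < 0 for f in self.location_factors):
            raise ConfigError(f"library {self.name}: rates must be nonnegative")
        if self.n_reads is not None and self.n_reads <= 0:
            raise ConfigError(f"library {self.name}: n_reads must be positive")


@dataclass
class SimConfig:
    """Full description of one synthetic study.

    The genome is split into ``n_chromosomes`` equal chromosomes.  Genes are
    laid out with at least ``gene_spacing`` bp between spans; each gene has
    ``exons_per_gene`` exons of ``exon_length`` bp separated by introns of
    ``intron_length`` bp.  The proximal placement band spans
    ``proximal_band`` bp from a gene edge and distal placements are at least
    ``distal_floor`` bp from every gene.  ``young_proximal_bias`` tilts the
    placement of low-divergence copies towards the proximal band (and of
    high-divergence copies away from it) to emulate the empirical coupling
    between element age and gene proximity.
    """

    genome_length: int
    n_chromosomes: int
    families: list[FamilySpec]
    n_genes: int
    libraries: list[LibrarySpec]
    seed: int = 0
    exons_per_gene: int = 4
    exon_length: int = 300
    intron_length: int = 7000
    gene_spacing: int = 45_000
    proximal_band: tuple[int, int] = (1_000, 20_000)
    distal_floor: int = 50_000
    expression_lognormal_params: tuple[float, float] = (3.0, 1.5)
    young_proximal_bias: float = 0.0
    chrom_lead: int = 70_000

    def validate(self) -> None:
        if self.genome_length <= 0 or self.n_chromosomes <= 0:
            raise ConfigError("genome_length and n_chromosomes must be positive")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be nonnegative")
        if not self.families:
            raise ConfigError("at least one family is required")
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigError(f"duplicate family name(s): {', '.join(dupes)}")
        for f in self.families:
            f.validate()
        lib_names = [l.name for l in self.libraries]
        if len(set(lib_names)) != len(lib_names):
            raise ConfigError("duplicate library names")
        for l in self.libraries:
            l.validate()
        if not 0 <= self.young_proximal_bias <= 1:
            raise ConfigError("young_proximal_bias must lie in [0, 1]")
        lo, hi = self.proximal_band
        if not 0 < lo < hi:
            raise ConfigError("proximal_band must be an increasing positive range")
        if self.distal_floor <= hi:
            raise ConfigError("distal_floor must exceed the proximal band")

    @property
    def gene_length(self) -> int:
        n_introns = max(self.exons_per_gene - 1, 0)
        return self.exons_per_gene * self.exon_length + n_introns * self.intron_length


@dataclass
class AnalysisConfig:
    """Knobs of the analysis pipeline (defaults follow the method)."""

    complexity_threshold: float = 0.75
    complexity_window: int = 16
    min_read_length: int = 16
    tss_radius: int = 1000
    remove_tss_reads: bool = False
    tss_mode: str = "any"  # 'any' or 'all' mappings near a TSS -> drop read
    overlap_mode: str = "contained"  # or 'any'
    min_loci_per_family: int = 1000
    min_families_for_test: int = 5
    gene_flank: int = 10_000
    isolation_gap: int = 20_000
    n_correction: int | None = None  # None -> number of contrasts actually run
    pseudocount: float = 0.5
    index_k: int = 16
    tss_profile_half_width: int = 2000
    tss_profile_bin: int = 10


@dataclass
class RunConfig:
    """A simulation plus the analysis settings applied to it."""

    sim: SimConfig
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def _tupleize(obj):
    if isinstance(obj, list):
        return tuple(_tupleize(x) for x in obj)
    return obj


def _family_from_dict(d: dict) -> FamilySpec:
    d = dict(d)
    for key in ("millidiv_range", "placement_probs"):
        if key in d:
            d[key] = _tupleize(d[key])
    return FamilySpec(**d)


def _library_from_dict(d: dict) -> LibrarySpec:
    d = dict(d)
    for key in ("location_factors", "read_length_range"):
        if key in d:
            d[key] = _tupleize(d[key])
    return LibrarySpec(**d)


def sim_config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    d["families"] = [_family_from_dict(f) for f in d.get("families", [])]
    d["libraries"] = [_library_from_dict(l) for l in d.get("libraries", [])]
    for key in ("proximal_band", "expression_lognormal_params"):
        if key in d:
            d[key] = _tupleize(d[key])
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg


def run_config_from_dict(d: dict) -> RunConfig:
    sim = sim_config_from_dict(d["sim"])
    analysis = AnalysisConfig(**d.get("analysis", {}))
    return RunConfig(sim=sim, analysis=analysis)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "sim" not in doc:
        # A bare simulation document is also accepted.
        doc = {"sim": doc}
    return run_config_from_dict(doc)


def dump_config(cfg: RunConfig, path) -> None:
    doc = {"sim": asdict(cfg.sim), "analysis": asdict(cfg.analysis)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
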