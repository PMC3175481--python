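"""Annotation parsing and validation.

Handles RepeatMasker ``.out`` repeat annotations, BED12 gene models, simple
two-column expression tables, and the derivation of a non-overlapping TSS
set.  All coordinates are converted to 0-based half-open on the way in;
every writer states its convention explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class RteLocus:
    """One annotated retrotransposon interval.

    ``millidiv`` is the divergence from the family consensus in substitutions
    per 1000 bp (RepeatMasker "perc div" times ten) and serves as the age
    proxy throughout the analysis.
    """

    locus_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    family: str
    superfamily: str
    rte_type: str
    millidiv: float

    def __post_init__(self):
        if self.start >= self.end:
            raise AnnotationError(f"{self.locus_id}: empty or inverted interval")
        if self.strand not in STRANDS:
            raise AnnotationError(f"{self.locus_id}: strand must be '+' or '-'")
        if self.millidiv < 0:
            raise AnnotationError(f"{self.locus_id}: negative millidiv")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """One gene (single representative transcript): span, TSS, expression."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int
    exon_starts: tuple[int, ...] = ()
    exon_ends: tuple[int, ...] = ()
    expression: float | None = None

    def __post_init__(self):
        if not self.start <= self.tss < self.end:
            raise AnnotationError(f"{self.gene_id}: TSS outside gene span")
        if self.strand not in STRANDS:
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def stop_site(self) -> int:
        """Transcription end point (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class TssRecord:
    gene_id: str
    chrom: str
    position: int
    strand: str


def classify_rte_type(repeat_class: str, repeat_name: str = "") -> str:
    """Route a RepeatMasker class/family string to one of the four RTE types.

    LTR annotations split in two: internal sequences (repeat names suffixed
    ``-int``) versus terminal repeats.  Anything that is not a
    retrotransposon (DNA transposons, simple repeats, ...) maps to OTHER and
    is excluded downstream.
    """
    head = repeat_class.split("/", 1)[0].strip()
    if head == "LINE":
        return "LINE"
    if head == "SINE":
        return "SINE"
    if head == "LTR":
        name = repeat_name.strip()
        if name.endswith("-int") or repeat_class.strip().endswith("-int"):
            return "LTRint"
        return "LTRter"
    return "OTHER"


def _superfamily(repeat_class: str) -> str:
    parts = repeat_class.split("/", 1)
    return parts[1].strip() if len(parts) == 2 else parts[0].strip()


def read_repeatmasker_out(path, keep_other: bool = False) -> list[RteLocus]:
    """Parse a RepeatMasker ``.out`` file into RTE loci.

    The standard layout is whitespace-delimited with up to three header
    lines.  Query coordinates are 1-based inclusive and become 0-based
    half-open; strand ``C`` becomes ``-``; the "perc div" column times ten
    becomes millidivergence.  Rows of non-retrotransposon classes are
    dropped unless ``keep_other`` is set.  More than 10% malformed rows is
    treated as a parse error.
    """
    loci: list[RteLocus] = []
    bad: list[int] = []
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            first = stripped.split()[0]
            if lineno <= 3 and not first.replace(".", "").isdigit():
                continue  # header lines
            n_rows += 1
            fields = stripped.split()
            try:
                perc_div = float(fields[1])
                chrom = fields[4]
                start = int(fields[5]) - 1
                end = int(fields[6])
                strand = {"+": "+", "C": "-", "-": "-"}[fields[8]]
                name = fields[9]
                repeat_class = fields[10]
                if perc_div < 0 or start < 0 or start >= end:
                    raise ValueError("bad coordinates or divergence")
            except (IndexError, KeyError, ValueError):
                bad.append(lineno)
                continue
            rte_type = classify_rte_type(repeat_class, name)
            if rte_type == "OTHER" and not keep_other:
                continue
            loci.append(
                RteLocus(
                    locus_id=f"rm{lineno}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    family=name,
                    superfamily=_superfamily(repeat_class),
                    rte_type=rte_type,
                    millidiv=round(perc_div * 10, 2),
                )
            )
    if n_rows and len(bad) / n_rows > 0.10:
        raise AnnotationError(
            f"{path}: {len(bad)}/{n_rows} malformed rows (lines {bad[:20]}{'...' if len(bad) > 20 else ''})"
        )
    if bad:
        warnings.warn(f"{path}: skipped {len(bad)} malformed row(s) at lines {bad}")
    return loci


_RM_HEADER = (
    "   SW   perc perc perc  query                position in query     matching"
    "            repeat               position in repeat\n"
    "score   div. del. ins.  sequence             begin  end    (left)  repeat"
    "              class/family       begin  end    (left)  ID\n"
    "\n"
)


def write_repeatmasker_out(loci, path) -> None:
    """Write loci in the 15-column RepeatMasker ``.out`` layout.

    Coordinates go out 1-based inclusive; millidiv is written as the
    "perc div" column (divided by ten, two decimals, which round-trips the
    one-decimal millidivergences the simulator produces); minus strand is
    written as ``C``.  Alignment-score and repeat-coordinate columns carry
    placeholders: this writer exists to feed the parser and external tools
    that only consume the query-side columns.
    """
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, loc in enumerate(loci, start=1):
            repeat_class = {
                "LINE": f"LINE/{loc.superfamily}",
                "SINE": f"SINE/{loc.superfamily}",
                "LTRint": f"LTR/{loc.superfamily}",
                "LTRter": f"LTR/{loc.superfamily}",
            }.get(loc.rte_type, loc.superfamily)
            strand = "+" if loc.strand == "+" else "C"
            fh.write(
                f"{1000:>5} {loc.millidiv / 10:6.2f} {0.0:4.1f} {0.0:4.1f}  "
                f"{loc.chrom:<12} {loc.start + 1:>8} {loc.end:>8} (0) "
                f"{strand} {loc.family:<18} {repeat_class:<18} {1:>6} "
                f"{loc.length:>6} (0) {i:>5}\n"
            )


def read_bed12_genes(path, expression: dict[str, float] | None = None) -> list[GeneModel]:
    """Read gene models from BED12 (0-based half-open; one transcript/row)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise AnnotationError(f"{path}:{lineno}: expected 12 BED columns, got {len(f)}")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exon_starts = tuple(start + o for o in offsets)
            exon_ends = tuple(s + sz for s, sz in zip(exon_starts, sizes))
            tss = start if strand == "+" else end - 1
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    tss=tss,
                    exon_starts=exon_starts,
                    exon_ends=exon_ends,
                    expression=None if expression is None else expression.get(name),
                )
            )
    return genes


def write_bed12_genes(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in zip(g.exon_starts, g.exon_ends))
            offsets = ",".join(str(s - g.start) for s in g.exon_starts)
            n = len(g.exon_starts)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{n}\t{sizes}\t{offsets}\n"
            )


def select_tss(transcripts: pd.DataFrame) -> list[TssRecord]:
    """Pick one TSS per gene from transcript start points.

    ``transcripts`` needs columns ``gene_id, chrom, strand, start`` where
    ``start`` is the transcriptional start coordinate of one transcript.
    Per gene the modal start wins; ties go to the most upstream candidate in
    transcriptional orientation (smallest coordinate on '+', largest on '-').
    """
    required = {"gene_id", "chrom", "strand", "start"}
    missing = required - set(transcripts.columns)
    if missing:
        raise AnnotationError(f"select_tss: missing columns {sorted(missing)}")
    records: list[TssRecord] = []
    for gene_id, grp in transcripts.groupby("gene_id", sort=True):
        if grp.empty:
            continue
        strand = grp["strand"].iloc[0]
        chrom = grp["chrom"].iloc[0]
        counts = grp["start"].value_counts()
        top = counts[counts == counts.max()].index
        pos = int(top.min() if strand == "+" else top.max())
        records.append(TssRecord(gene_id=gene_id, chrom=chrom, position=pos, strand=strand))
    return records


def tss_from_genes(genes) -> list[TssRecord]:
    return [TssRecord(g.gene_id, g.chrom, g.tss, g.strand) for g in genes]


def write_tss_bed6(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.position}\t{r.position + 1}\t{r.gene_id}\t0\t{r.strand}\n")


def read_expression(path) -> dict[str, float]:
    """Read a 2+-column TSV (gene_id, signal) with header; duplicates average."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header:
            warnings.warn(f"{path}: empty expression table")
            return {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationError(f"{path}:{lineno}: expected at least 2 columns")
            gene_id = fields[0]
            try:
                signal = float(fields[1])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}:{lineno}: non-numeric signal {fields[1]!r}"
                ) from exc
            sums[gene_id] = sums.get(gene_id, 0.0) + signal
            counts[gene_id] = counts.get(gene_id, 0) + 1
    return {g: sums[g] / counts[g] for g in sums}


def write_expression(expr: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsignal\n")
        for gene_id in sorted(expr):
            fh.write(f"{gene_id}\t{expr[gene_id]:.6g}\n")


def loci_frame(loci) -> pd.DataFrame:
    """Tabular view of a locus list (one row per locus, indexed by locus_id)."""
    df = pd.DataFrame(
        {
            "locus_id": [l.locus_id for l in loci],
            "chrom": [l.chrom for l in loci],
            "start": [l.start for l in loci],
            "end": [l.end for l in loci],
            "strand": [l.strand for l in loci],
            "family": [l.family for l in loci],
            "superfamily": [l.superfamily for l in loci],
            "rte_type": [l.rte_type for l in loci],
            "millidiv": [l.millidiv for l in loci],
        }
    )
    df["length"] = df["end"] - df["start"]
    df["midpoint"] = (df["start"] + df["end"]) // 2
    df = df.set_index("locus_id", drop=False)
    df.index.name = None
    return df
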