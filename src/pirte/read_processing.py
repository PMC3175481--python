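"""Small-RNA read filtering and perfect-match multi-mapping.

Reads are kept only if they are unambiguous (A/C/G/T) and linguistically
complex enough; surviving reads are matched against the genome exactly, on
both strands, and every read carries its full set of genomic mappings.  The
reciprocal of the mapping count is the weight used by the coverage engine,
so the mapper must enumerate *all* perfect matches — it is implemented as a
seed-and-verify search over a sorted 2-bit k-mer index and is contractually
equivalent to a brute-force scan.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pysam
from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ReadMappingSet:
    """All perfect genomic matches of one read.

    ``multiplicity`` (the number of mappings, both strands) is the
    denominator of the per-read weight 1/multiplicity.  Minus-strand
    mappings are reported at the leftmost genomic coordinate of the match.
    """

    read_id: str
    length: int
    mappings: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def multiplicity(self) -> int:
        return len(self.mappings)

    @property
    def mapped(self) -> bool:
        return bool(self.mappings)


@dataclass
class FilterReport:
    n_raw: int = 0
    n_ambiguous_removed: int = 0
    n_low_complexity_removed: int = 0

    @property
    def n_kept(self) -> int:
        return self.n_raw - self.n_ambiguous_removed - self.n_low_complexity_removed

    @property
    def fraction_filtered(self) -> float:
        if self.n_raw == 0:
            return 0.0
        return (self.n_ambiguous_removed + self.n_low_complexity_removed) / self.n_raw


def has_ambiguous(sequence: str) -> bool:
    """True iff the sequence contains any character outside A/C/G/T."""
    return any(c not in "ACGT" for c in sequence.upper())


def linguistic_complexity(window: str) -> float:
    """Linguistic complexity: the fraction of the maximum substring
    vocabulary a sequence realizes.

    Counts the distinct subwords of every length k = 1..L and divides by
    the largest vocabulary a length-L sequence could have,
    ``sum_k min(4**k, L-k+1)``.  A random 16-bp window scores ~0.96; a
    homopolymer 16/124 ~ 0.13; a dinucleotide repeat ~0.25 — so the 0.75
    threshold removes repetitive reads while leaving typical sequence
    essentially untouched.
    """
    L = len(window)
    if L < 2:
        raise ValueError("linguistic complexity needs a window of length >= 2")
    window = window.upper()
    max_vocab, tails = _vocab_constants(L)
    observed = len(set(window))
    for k in range(2, L + 1):
        n_sub = L - k + 1
        dk = len({window[i : i + k] for i in range(n_sub)})
        observed += dk
        if dk == n_sub:
            # All k-mers distinct: any repeated longer subword would repeat
            # a k-mer, so every remaining length contributes its maximum.
            observed += tails[k + 1]
            break
    return observed / max_vocab


@lru_cache(maxsize=None)
def _vocab_constants(L: int):
    """(max vocabulary size, tail sums) for a window of length L.

    ``tails[k]`` is the total subword count for lengths k..L when every
    subword is distinct, i.e. sum of (L-j+1) for j >= k.
    """
    max_vocab = sum(min(4**k, L - k + 1) for k in range(1, L + 1))
    tails = [0] * (L + 2)
    for k in range(L, 0, -1):
        tails[k] = tails[k + 1] + (L - k + 1)
    return max_vocab, tuple(tails)


def mean_complexity(sequence: str, window: int = 16) -> float:
    """Average linguistic complexity over sliding windows (step 1).

    Reads shorter than the window are scored as a single window.
    """
    L = len(sequence)
    if L < 2:
        raise ValueError("mean complexity needs a read of length >= 2")
    if L <= window:
        return linguistic_complexity(sequence)
    values = [linguistic_complexity(sequence[i : i + window]) for i in range(L - window + 1)]
    return sum(values) / len(values)


def filter_reads(
    reads, complexity_threshold: float = 0.75, window: int = 16
) -> tuple[list[ReadRecord], FilterReport]:
    """Drop ambiguous-base reads, then low-complexity reads.

    Returns the surviving reads and a tally.  Idempotent: filtering its own
    output removes nothing.
    """
    if not 0 < complexity_threshold <= 1:
        raise ValueError("complexity_threshold must lie in (0, 1]")
    report = FilterReport()
    kept: list[ReadRecord] = []
    for read in reads:
        report.n_raw += 1
        seq = read.sequence.upper()
        if has_ambiguous(seq):
            report.n_ambiguous_removed += 1
            continue
        if mean_complexity(seq, window=window) < complexity_threshold:
            report.n_low_complexity_removed += 1
            continue
        kept.append(ReadRecord(read.read_id, seq))
    return kept, report


class GenomeIndex:
    """Sorted 2-bit k-mer index over a genome for exact-match queries.

    Each k-mer of the genome is packed into a 64-bit code (collision-free
    for k <= 31); codes are sorted with their positions so a query is two
    binary searches.  Seed hits are verified by direct string comparison, so
    the index parameter only affects speed, never results.  Queries shorter
    than k fall back to a full scan.
    """

    def __init__(self, genome: dict[str, str], k: int = 16):
        if not 1 <= k <= 31:
            raise ValueError("index k must lie in [1, 31]")
        self.k = k
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.chroms = sorted(self.genome)
        codes_all = []
        pos_all = []
        chrom_idx_all = []
        for ci, chrom in enumerate(self.chroms):
            seq = self.genome[chrom]
            if len(seq) < k:
                continue
            codes, valid = _pack_kmers(seq, k)
            pos = np.nonzero(valid)[0]
            codes_all.append(codes[pos])
            pos_all.append(pos)
            chrom_idx_all.append(np.full(len(pos), ci, dtype=np.int32))
        if codes_all:
            codes = np.concatenate(codes_all)
            order = np.argsort(codes, kind="stable")
            self._codes = codes[order]
            self._pos = np.concatenate(pos_all)[order]
            self._chrom_idx = np.concatenate(chrom_idx_all)[order]
        else:
            self._codes = np.empty(0, dtype=np.uint64)
            self._pos = np.empty(0, dtype=np.int64)
            self._chrom_idx = np.empty(0, dtype=np.int32)

    def _seed_hits(self, kmer: str):
        code = _pack_query(kmer)
        if code is None:
            return ()
        lo = np.searchsorted(self._codes, code, side="left")
        hi = np.searchsorted(self._codes, code, side="right")
        return zip(self._chrom_idx[lo:hi], self._pos[lo:hi])

    def _find_forward(self, seq: str) -> list[tuple[str, int]]:
        hits: list[tuple[str, int]] = []
        if len(seq) < self.k:
            for chrom in self.chroms:
                ref = self.genome[chrom]
                i = ref.find(seq)
                while i != -1:
                    hits.append((chrom, i))
                    i = ref.find(seq, i + 1)
            return hits
        for ci, pos in self._seed_hits(seq[: self.k]):
            chrom = self.chroms[ci]
            ref = self.genome[chrom]
            p = int(pos)
            if ref[p : p + len(seq)] == seq:
                hits.append((chrom, p))
        return hits

    def map_sequence(self, read_id: str, sequence: str) -> ReadMappingSet:
        """All perfect matches of the read on both strands."""
        seq = sequence.upper()
        mappings = [(c, p, "+") for c, p in self._find_forward(seq)]
        mappings += [(c, p, "-") for c, p in self._find_forward(revcomp(seq))]
        mappings = sorted(set(mappings))
        return ReadMappingSet(read_id=read_id, length=len(seq), mappings=mappings)


def _pack_kmers(seq: str, k: int):
    """Vectorized 2-bit packing of all k-mers of ``seq``.

    Returns (codes, valid) of length len(seq)-k+1; ``valid`` is False for
    windows containing non-ACGT characters.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    base = np.full(raw.shape, 255, dtype=np.uint8)
    for value, ch in enumerate(b"ACGT"):
        base[raw == ch] = value
    n = len(seq) - k + 1
    codes = np.zeros(n, dtype=np.uint64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        b = base[j : j + n]
        ok &= b != 255
        codes = (codes << np.uint64(2)) | b.astype(np.uint64)
    return codes, ok


def _pack_query(kmer: str):
    code = 0
    for ch in kmer:
        v = "ACGT".find(ch)
        if v == -1:
            return None
        code = (code << 2) | v
    return np.uint64(code)


def map_exact(index: GenomeIndex, read: ReadRecord) -> ReadMappingSet:
    """Map one filtered read; see :meth:`GenomeIndex.map_sequence`."""
    return index.map_sequence(read.read_id, read.sequence)


def map_reads(index: GenomeIndex, reads) -> tuple[list[ReadMappingSet], list[str]]:
    """Map a read list, deduplicating identical sequences internally.

    Returns mapping sets for mapped reads (one per read record, not per
    unique sequence) and the ids of unmapped reads.
    """
    by_seq: dict[str, ReadMappingSet] = {}
    mapped: list[ReadMappingSet] = []
    unmapped: list[str] = []
    for read in reads:
        seq = read.sequence.upper()
        hit = by_seq.get(seq)
        if hit is None:
            hit = index.map_sequence(read.read_id, seq)
            by_seq[seq] = hit
        if hit.mapped:
            mapped.append(ReadMappingSet(read.read_id, len(seq), hit.mappings))
        else:
            unmapped.append(read.read_id)
    return mapped, unmapped


def read_fastx(path) -> list[ReadRecord]:
    """Read FASTA or FASTQ (by extension; .gz tolerated) into ReadRecords."""
    import gzip

    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq", ".fastq.gz", ".fq.gz")) else "fasta"
    opener = gzip.open if p.endswith(".gz") else open
    with opener(p, "rt") as fh:
        return [ReadRecord(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, fmt)]


def write_fasta_reads(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def write_fastq_reads(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")


def ingest_alignments(path, trust_perfect: bool = False) -> list[ReadMappingSet]:
    """Build mapping sets from an external SAM or BED6 alignment file.

    Records with a nonzero edit distance (SAM ``NM`` tag) are dropped to
    honour the perfect-match contract; multiplicity is then recomputed as
    the number of surviving records per read id.  Secondary/supplementary
    records count.  SAM records lacking ``NM`` are kept only under
    ``trust_perfect`` (with a warning otherwise they are dropped).
    """
    p = str(path)
    if p.endswith(".bed"):
        return _ingest_bed(p)
    sets: dict[str, ReadMappingSet] = {}
    warned = False
    with pysam.AlignmentFile(p, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.has_tag("NM"):
                if rec.get_tag("NM") != 0:
                    continue
            elif not trust_perfect:
                if not warned:
                    warnings.warn(
                        f"{path}: records without NM tags dropped; pass trust_perfect=True "
                        "if the aligner already enforced perfect matches"
                    )
                    warned = True
                continue
            strand = "-" if rec.is_reverse else "+"
            key = rec.query_name
            ms = sets.setdefault(key, ReadMappingSet(key, rec.query_length or rec.infer_query_length() or 0))
            if ms.length == 0 and rec.query_length:
                ms.length = rec.query_length
            entry = (rec.reference_name, rec.reference_start, strand)
            if entry not in ms.mappings:
                ms.mappings.append(entry)
    return [s for s in sets.values() if s.mapped]


def _ingest_bed(path) -> list[ReadMappingSet]:
    sets: dict[str, ReadMappingSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 required")
            if f[5] not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand required, got {f[5]!r}")
            chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
            ms = sets.setdefault(name, ReadMappingSet(name, end - start))
            entry = (chrom, start, strand)
            if entry not in ms.mappings:
                ms.mappings.append(entry)
    return [s for s in sets.values() if s.mapped]


def write_mappings_bed6(mapping_sets, path) -> None:
    """Export mappings as BED6 with the multiplicity in the score column."""
    with open(path, "w") as fh:
        for ms in mapping_sets:
            for chrom, start, strand in ms.mappings:
                fh.write(
                    f"{chrom}\t{start}\t{start + ms.length}\t{ms.read_id}\t{ms.multiplicity}\t{strand}\n"
                )


def remove_tss_proximal(
    mapping_sets, tss_records, radius: int = 1000, mode: str = "any"
) -> list[ReadMappingSet]:
    """Drop reads whose mappings fall within ``radius`` bp of an annotated TSS.

    A mapping is TSS-proximal when the distance between its interval and the
    TSS point is <= radius.  ``mode='any'`` (default) drops a read if any of
    its mappings is proximal; ``mode='all'`` only if all are.  Multiplicities
    of retained reads are untouched: the weight denominator is the genomic
    mapping count, not the count of surviving mappings.
    """
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    if mode not in ("any", "all"):
        raise ValueError("mode must be 'any' or 'all'")
    tss_by_chrom: dict[str, np.ndarray] = {}
    for r in tss_records:
        tss_by_chrom.setdefault(r.chrom, []).append(r.position)  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in tss_by_chrom.items()}

    def proximal(chrom: str, start: int, length: int) -> bool:
        positions = tss_by_chrom.get(chrom)
        if positions is None or len(positions) == 0:
            return False
        end = start + length - 1  # last covered base
        i = int(np.searchsorted(positions, start))
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                t = int(positions[j])
                dist = 0 if start <= t <= end else min(abs(t - start), abs(t - end))
                if dist <= radius:
                    return True
        # A TSS strictly inside the interval is caught by neighbours only if
        # the interval is short; check the covering range explicitly.
        lo = int(np.searchsorted(positions, start))
        hi = int(np.searchsorted(positions, end, side="right"))
        return hi > lo

    kept = []
    for ms in mapping_sets:
        flags = [proximal(c, s, ms.length) for c, s, _ in ms.mappings]
        drop = any(flags) if mode == "any" else all(flags)
        if not drop:
            kept.append(ms)
    return kept


def length_histogram(reads) -> dict[int, int]:
    """Exact counts of read lengths."""
    return dict(sorted(Counter(len(r.sequence) for r in reads).items()))
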