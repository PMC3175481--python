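# Methods

This note documents the models, conventions and numerical choices behind
`pirte`: what the pipeline computes, what the synthetic-data generator
emulates (and what it deliberately does not), and where the design was
genuinely open.

## Coverage model

The unit of analysis is the annotated RTE locus (one RepeatMasker `.out`
row; fragmented hits of one insertion are *not* merged).  For a library of
N mapped reads, the coverage of locus *i* of length `L_i` is

    C_i = (Σ_{r contained in i} 1/m(r)) / (L_i/1000) / (N/10^6),

with `m(r)` the number of perfect genomic mappings of read `r` over both
strands.  Conventions:

- **Containment**: a mapping contributes to a locus only if its aligned
  interval lies fully inside the locus interval (`overlap_mode="contained"`,
  the default; `"any"` is available for sensitivity analysis).
- **Weights are read properties**: `m(r)` is fixed at mapping time and is
  not recomputed when reads are restricted to a subset (e.g. the
  superfamily-exclusive analyses) or when TSS-proximal reads are removed.
- A read contained in two overlapping loci contributes its weight to both;
  no apportioning.  Consequently Σ_i raw_i ≤ N, with equality exactly when
  every mapping of every read is contained in exactly one locus.
- **Library size** N = number of reads with ≥ 1 perfect match after all
  filters (including TSS-read removal when enabled).
- Palindromic reads count one mapping per strand at the same position;
  minus-strand mappings are reported at the leftmost genomic coordinate.

The exact mapper packs genome k-mers (default k = 16) into 64-bit codes,
sorts them, and answers queries with two binary searches followed by
literal string verification, so the index parameter affects speed only.
Queries shorter than k fall back to a full scan.  Equivalence with a naive
full scan is asserted by tests on randomized instances.

## Read filtering

Reads with any non-ACGT character are removed first.  Remaining reads are
scored by linguistic complexity averaged over sliding 16-bp windows and
dropped below 0.75.  The complexity of a window of length L is the
vocabulary ratio

    LC = (Σ_k distinct subwords of length k) / (Σ_k min(4^k, L−k+1)),

summed over k = 1..L.  Random 16-mers score ≈ 0.96, homopolymers 16/124 ≈
0.13, dinucleotide repeats ≈ 0.25, so the 0.75 threshold removes highly
repetitive reads and essentially nothing else — consistent with a filter
that touches well under 1% of a real library.  (A product-of-usages
complexity variant was considered and rejected: it scores *random* windows
near 0.64, which would make a 0.75 threshold discard most of a library.)

## Locus grouping

- **Age tertiles** per family: loci sorted by millidivergence (ties broken
  by locus id for determinism) and split young/median/old; remainder loci
  go to the younger groups, so sizes differ by at most one.  Families with
  fewer than 3 loci are skipped.
- **Location classes**: *genic* iff the locus midpoint lies inside any gene
  span (start–stop, introns included).  Midpoint membership — rather than
  full containment — guarantees one class per locus and settles
  boundary-straddling insertions.  For non-genic loci the distance is
  midpoint to nearest gene-span edge; the proximal/distal border is the
  family median of these distances, with ties at the median assigned
  proximal.  Chromosomes without genes yield infinite distances (distal).
- **Gene-relative orientation**: forward iff locus strand equals the host
  gene strand; the host is the innermost span containing the midpoint
  (smallest gene id on ties).

## Statistical testing

Per family and library, mean coverage is computed for each of the 9
(age × location) cells; empty cells are missing, not zero.  For every
contrast (RTE type × age group × location pair × library — 108 in the full
three-library design) the per-family cell-mean pairs feed a two-sided
Wilcoxon signed-rank test (scipy): zero differences dropped, exact null for
n ≤ 25 without ties, tie-corrected normal approximation otherwise.
Contrasts with fewer than 5 informative pairs are flagged underpowered and
reported non-significant.  The familywise correction is the Šidák-form
`p_corrected = 1 − (1−p)^n` (evaluated as `-expm1(n·log1p(-p))` for
stability), with n defaulting to the number of contrasts actually run and
overridable (`n_correction`).  Direction is the sign of the median paired
difference; tiers are 0.05 and 0.001 on the corrected p.

Expression-group comparisons (isolated genes only, ≥ 20 kb to the nearest
neighbour) use two-sided Mann-Whitney U (exact for small tie-free samples).
Expression quartiles take the top/bottom ⌊n/4⌋ genes; ties at a boundary
fall to the medium group, so group sizes may deviate from exact quarters.
Gene windows run from 10 kb upstream of the TSS to 10 kb past the stop
site; window coverage is normalized by the RTE base pairs (per type) the
window overlaps.

Strand bias is `log2((sense + ½)/(antisense + ½))` over uniquely mapping
reads, with counts summed over loci per (type × orientation × library)
before the ratio (Haldane–Anscombe pseudocount; the ratio is otherwise
undefined at zero counts).

TSS metaprofiles bin mapping start positions within ±2 kb of each TSS
(10-bp bins), orientation-normalized (positive = downstream in
transcription direction), strand taken relative to the gene, weighted by
1/m(r), and split by whether the mapping lies inside an RTE locus.

## The synthetic-data generator

The generator emulates the structure the analysis assumes, at desk scale:

- **Families and copies.**  Each family has a random consensus; each copy
  is the consensus with exactly `round(millidiv/1000 · L)` point
  substitutions at distinct positions, so the annotated millidivergence is
  the realized divergence, not an estimate.  No indels — this keeps ages
  exact and parsing alignment-free.  Low-divergence copies of a family are
  near-identical, which is precisely the multi-mapping substrate the 1/m
  weighting exists for.
- **Genome layout.**  Genes (uniform exon/intron structure) are spaced
  ≥ 45 kb apart; copies are placed in introns (genic), 1–20 kb from a gene
  edge (proximal), or in a gene-free desert ≥ 50 kb from every gene
  (distal).  Planted intervals never overlap.  Because the planted bands
  sit well clear of the 20–50 kb gap, the analysis-side median split
  re-derives the planted classes for ~96% of loci (the residual mismatch
  is the median split forcing a within-family 50:50 proximal:distal
  balance that a finite multinomial draw cannot always honour).
- **Read model.**  Per-locus counts are Poisson with mean
  `base_rate · exp(−age_decay · millidiv) · location_factor(class)` — the
  minimal distributional choice for proportional sampling.  Read starts
  are uniform within the locus, lengths uniform in 24–30 nt, never
  extending past locus ends; loci shorter than 16 nt are skipped with a
  warning.  Reads are literal genome substrings (reverse-complemented for
  minus-strand origin).
- **Strand coupling.**  Genic reads are emitted from the host gene's
  transcribed strand with probability `host_strand_coupling`
  (co-transcription); non-genic reads from the element strand with
  probability `sense_fraction_nongenic`.
- **Age–location coupling.**  `young_proximal_bias` b rescales the
  proximal weight by `1 + b(1−2u)` and the distal weight by `1 + b(2u−1)`,
  where u is the copy's position in the family's millidivergence range.
  The default b = 0.7 makes ~95% of families show a higher proximal
  fraction among young than old loci, matching the strength of the
  empirical age–proximity coupling in real annotation.
- **Determinism.**  One integer seed drives everything through
  `numpy.random.SeedSequence` spawning; a fixed seed fixes every output
  byte (FASTA, `.out`, BED12, TSV).

### Stock configurations (the study conditions)

| config | purpose | size |
|---|---|---|
| `default` | full study: 4 RTE types × 18 families × 81 copies (5832 loci), 48 genes, 5 Mb over 2 chromosomes, three libraries (two prenatal-profile with coupling 0.5, one postnatal-profile with coupling 0.9 and a higher genic rate), age decay ln 8/300 (8-fold young:old across the 0–300 millidiv range), location factors (2,4,1) early / (4,4,1) late | ~120k reads |
| `small` | ≤ 1 Mb / ≤ 5k-read variant for oracle and determinism checks | 240 loci |
| `null` | no planted effects: flat location factors, zero age decay, no placement bias | 576 loci |
| `strand` | high-divergence (100–400 millidiv) copies so most reads map uniquely; used for strand-bias recovery | 288 loci |

These sizes are desk-scale stand-ins for the genome-wide originals: the
family-size floor for family-level summaries is 30 here (default 1000 at
genome scale), and library sizes are tens of thousands of reads rather
than millions.  Rates, couplings and the 4:1/8:1 effect sizes are the
package's fixed test conditions, not claims about mouse biology.

### What the generator does not emulate

No indels or recombination (hence no solitary-LTR formation), no ping-pong
amplification or 10-nt overlap signature, no exonic insertions (genic
copies are intronic only), no expression-coupled read rates, no sequencing
errors or adapter remnants, and no strain polymorphism.  Passing tests
therefore demonstrate the correctness of the *analysis machinery* and the
recoverability of planted effects — not the biological fidelity of any
particular rate model.

## Numerical choices

- Percentiles: numpy's linear interpolation; medians by the midpoint rule.
- Exact rank tests switch to approximations exactly when scipy's do
  (ties, n > 25 for the signed-rank exact null).
- Coverage normalizations are plain double arithmetic; the oracle
  comparison tolerance is 1e-9.
- RepeatMasker round-trip: millidivergences are generated at one-decimal
  resolution and written as two-decimal "perc div" values, which makes the
  write→parse round trip exact.
- TSV output uses a fixed column order and `%.10g` floats so identical
  seeds give byte-identical files.

## Known limitations

- `select_isolated_genes` is O(n²) per chromosome — fine for annotation
  sizes up to ~10⁴ genes, the intended scale here.
- The exclusivity analysis attributes a read to a scope only via full
  containment of all its mappings; reads with mappings outside any
  annotated locus are excluded from every scope.
- `ingest_alignments` trusts the aligner's `NM` tag; alignments without it
  are dropped unless `trust_perfect` is set.
- The pipeline holds mappings in memory; genomes beyond tens of megabases
  with millions of multi-mapping reads would need chunked processing.
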