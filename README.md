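# pirte — retrotransposon-centered analysis of piRNA targeting

`pirte` quantifies how strongly individual retrotransposable-element (RTE)
loci are targeted by Piwi-associated small RNAs (piRNAs, 24–30 nt) in
developing male germline tissue, and tests how that targeting depends on a
locus's age, its distance to protein-coding genes, and its orientation
relative to a host gene.  It is aimed at genomicists who want a tested,
reusable implementation of this locus-resolved targeting analysis — and a
synthetic-data generator that plants known effects so every stage can be
validated end to end.

## The statistic and the tests

RTE loci are highly redundant in sequence, so a piRNA read usually has many
perfect genomic matches and cannot be attributed to one locus.  The
pipeline therefore keeps **all** perfect matches of every read and weights
each read by the reciprocal of its genomic mapping count.  The *theoretical
piRNA coverage* of locus *i* in a library of *N* mapped reads is

```
            sum over reads r contained in locus i of  1 / m(r)
  C_i  =  ─────────────────────────────────────────────────────
                    (L_i / 1000) · (N / 10^6)
```

where `m(r)` is the number of perfect genomic mappings of read `r` and
`L_i` the locus length — weighted reads per kb of locus per million mapped
library reads.

Around this statistic the package implements:

- **Read filtering** — reads with ambiguous bases are dropped, then reads
  whose mean linguistic complexity over sliding 16-bp windows falls below
  0.75 (vocabulary-ratio form: distinct subwords of all lengths over the
  maximum possible).
- **Exact multi-mapping** — a sorted 2-bit k-mer index enumerates every
  perfect match on both strands; results are contractually identical to a
  brute-force scan (and tested against one).  External SAM/BED alignments
  can be ingested instead (perfect matches only, via the `NM` tag).
- **Locus grouping** — within each family, loci are split into age tertiles
  (young / median / old, by millidivergence from the family consensus) and,
  independently, into location classes: *genic* (midpoint inside a gene
  span), *proximal* / *distal* (non-genic loci below / above the family's
  median distance to the nearest gene).
- **Statistics** — per family the 3×3 (age × location) cell means feed
  paired Wilcoxon signed-rank tests across families: 4 RTE types × 3 age
  groups × 3 location pairs × 3 libraries = 108 contrasts, corrected with
  `p_corrected = 1 − (1 − p)^n`.  Expression-quartile contrasts use
  Mann-Whitney U; strand bias is the log2 ratio of sense to antisense
  uniquely-mapping read counts per (type × forward/reverse/nongenic).
- **Synthetic data** — genomes with gene models, RTE families whose copies
  carry an exactly realized millidivergence, Poisson read counts with
  age-decaying and location-dependent rates, and genic reads strand-coupled
  to the host gene.  Truth tables make every planted effect recoverable.

## Worked example

```python
from pirte.synthetic_data import simulate, stock_run_config
from pirte.pipeline import analyze

cfg = stock_run_config("default", seed=1)          # 72 families, 5832 loci
bundle, libraries = simulate(cfg.sim)              # 3 stage-profiled libraries
res = analyze(bundle.genome, bundle.loci, bundle.genes, bundle.expression,
              {l.name: l.reads for l in libraries}, cfg.analysis)

b = res.battery
pd_rows = b[(b.group_a == "proximal") & (b.group_b == "distal")]
print(len(b), (pd_rows.significance_tier != "ns").mean())
print(res.tables["proximal_fraction"].iloc[0].to_dict())
```

prints

```
108 1.0
{'fraction_families_young_higher': 0.9166666666666666, 'wilcoxon_p': 6.299758691146366e-13, 'n_families': 72.0}
```

i.e. all 108 contrasts were run, every proximal-vs-distal contrast is
corrected-significant under the planted 4:1 proximal:distal rate ratio, and
92% of the 72 families show a higher proximal fraction among their young
loci than among their old ones (paired Wilcoxon p ≈ 6e-13) under the
planted age–location coupling.

The same run from a shell, writing all figure-style TSVs
(`fig5_battery.tsv`, `fig7_strand_bias.tsv`, ...):

```
pirte run-all --config docs/example_config.yaml --seed 1 --outdir out/
```

(`pirte simulate` writes the generated genome/annotation/read files;
`pirte filter`, `pirte map` and `pirte validate` expose the individual
stages.)

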