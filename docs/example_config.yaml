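sim:
  genome_length: 1000000
  n_chromosomes: 1
  families:
  - name: L1Md_1
    superfamily: L1
    rte_type: LINE
    consensus_length: 300
    n_copies: 30
    millidiv_range:
    - 0.0
    - 300.0
    placement_probs:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
  - name: L2_1
    superfamily: L2
    rte_type: LINE
    consensus_length: 300
    n_copies: 30
    millidiv_range:
    - 0.0
    - 300.0
    placement_probs:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
  - name: B1_1
    superfamily: Alu
    rte_type: SINE
    consensus_length: 150
    n_copies: 30
    millidiv_range:
    - 0.0
    - 300.0
    placement_probs:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
  - name: B2_1
    superfamily: B2
    rte_type: SINE
    consensus_length: 150
    n_copies: 30
    millidiv_range:
    - 0.0
    - 300.0
    placement_probs:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
  - name: IAP1-int
    superfamily: ERVK
    rte_type: LTRint
    consensus_length: 280
    n_copies: 30
    millidiv_range:
    - 0.0
    - 300.0
    placement_probs:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
  - name: ERVL1-int
    superfamily: ERVL
    rte_type: LTRint
    consensus_length: 280
    n_copies: 30
    millidiv_range:
    - 0.0
    - 300.0
    placement_probs:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
  - name: IAP1-LTR
    superfamily: ERVK
    rte_type: LTRter
    consensus_length: 200
    n_copies: 30
    millidiv_range:
    - 0.0
    - 300.0
    placement_probs:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
  - name: ERVL1-LTR
    superfamily: ERVL
    rte_type: LTRter
    consensus_length: 200
    n_copies: 30
    millidiv_range:
    - 0.0
    - 300.0
    placement_probs:
    - 0.3333333333333333
    - 0.3333333333333333
    - 0.3333333333333333
  n_genes: 10
  libraries:
  - name: miwi2_early
    base_rate: 6.0
    age_decay: 0.006931471805599452
    location_factors:
    - 2.0
    - 4.0
    - 1.0
    host_strand_coupling: 0.5
    sense_fraction_nongenic: 0.5
    read_length_range:
    - 24
    - 30
    n_reads: null
  - name: mili_early
    base_rate: 6.0
    age_decay: 0.006931471805599452
    location_factors:
    - 2.0
    - 4.0
    - 1.0
    host_strand_coupling: 0.5
    sense_fraction_nongenic: 0.5
    read_length_range:
    - 24
    - 30
    n_reads: null
  - name: mili_late
    base_rate: 6.0
    age_decay: 0.006931471805599452
    location_factors:
    - 4.0
    - 4.0
    - 1.0
    host_strand_coupling: 0.9
    sense_fraction_nongenic: 0.5
    read_length_range:
    - 24
    - 30
    n_reads: null
  seed: 1
  exons_per_gene: 4
  exon_length: 250
  intron_length: 3000
  gene_spacing: 45000
  proximal_band:
  - 1000
  - 20000
  distal_floor: 50000
  expression_lognormal_params:
  - 3.0
  - 1.5
  young_proximal_bias: 0.7
  chrom_lead: 70000
analysis:
  complexity_threshold: 0.75
  complexity_window: 16
  min_read_length: 16
  tss_radius: 1000
  remove_tss_reads: false
  tss_mode: any
  overlap_mode: contained
  min_loci_per_family: 30
  min_families_for_test: 5
  gene_flank: 10000
  isolation_gap: 20000
  n_correction: null
  pseudocount: 0.5
  index_k: 16
  tss_profile_half_width: 2000
  tss_profile_bin: 10
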