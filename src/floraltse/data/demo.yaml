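# Bundled, fully synthetic demonstration configuration.
# One global seed drives every stochastic stage (fanned out per stage).
seed: 1

stages:
  synth: true
  annotate: true
  expression: true
  rarefaction: true
  lineages: true
  crossx: true
  qpcr: true

synth:
  n_families: 2000
  # birth/loss defaults (omit to use the built-in per-branch probabilities)
  zero_fraction: 0.2
  lognormal_mu: 2.0
  lognormal_sigma: 1.5
  n_reads: 100000
  mean_len: 316.0
  sd_len: 90.0
  n_replicates: 2
  chimera_fraction: 0.01
  utr_padding: true_utr
  complete_fraction: 0.7
  miss_rate: 0.0         # per-taxon hit-table drop rate
  spurious_rate: 0.0     # per-taxon spurious-hit rate
  read_miss_rate: 0.0
  qpcr_replicate_sd: 0.15
  qpcr_n_replicates: 6
  qpcr_n_outliers: 2
  qpcr_discordance_factor: 8.0
  microarray_expressed_fraction: 0.85
  microarray_multi_probe_fraction: 0.05

annotate:
  min_segment: 100
  max_overlap: 30
  max_evalue: 1.0e-10

expression:
  reference_gene: null   # null = the designed housekeeping reference
  min_count: 1
  exclude_chimeras: true

rarefaction:
  grid_points: 50
  mc: true               # resampled curve for the merged library
  reps: 1000
  theta: 1.0e-3
  plot: false

lineages:
  evalue_cutoff: 1.0e-10

crossx:
  detection_threshold: 100.0

qpcr:
  n_validation_genes: 14
  n_outlier_exclusions: 2
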