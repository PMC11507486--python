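# Example run-all configuration for `tgspipe run-all --config examples/config.yaml`.
# Exactly one input source: a `simulate:` block, or an `inputs:` block with
# vcf/phenotypes/panel paths.
seed: 42
out_dir: scratch/run_from_yaml
plots: true

simulate:
  n_cases: 211
  n_controls: 522
  n_variants: 2075
  block_size: 5
  within_block_rho: 0.8
  ld_block_fraction: 0.35
  missing_rate: 0.015
  n_related_pairs: 2
  n_sex_mismatch: 2

# inputs:
#   vcf: cohort.vcf
#   phenotypes: phenotypes.tsv
#   panel: panel.tsv
#   dosage_source: GT      # or a FORMAT field such as DS
#   info_key: null         # default: INFO then R2

qc:
  max_variant_missing: 0.02
  hwe_alpha: 0.05
  min_maf: 0.05
  min_info: 0.6
  max_sample_missing: 0.02
  max_relatedness: 0.125
  het_sd_k: 3.0
  hwe_scope: all           # or "controls"

clump:
  tiers: [0.05, 0.01]
  r2_threshold: 0.2
  window_bp: 250000

split:
  train_fraction: 0.8

evaluate:
  k_folds: 5
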