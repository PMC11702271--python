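# End-to-end demo: simulate an ascertained case/control cohort with an
# APOE-like major locus, QC it, build C+T scores from both discovery GWAS,
# fit the five risk models and compare individual-level scores.
seed: 42
simulate:
  n_variants: 800
  n_blocks: 40
  n_cases: 223
  n_controls: 345
  h2: 0.2
  prevalence: 0.05
qc:
  maf_min: 0.05
  miss_max: 0.05
  hwe_p_min: 1.0e-6
  info_min: 0.7
prs:
  r2_max: 0.1
  window_kb: 1000
models:
  scopes: [wholegenome, microglia]
  n_pcs: 8
consistency: {}
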