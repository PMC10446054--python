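# Example pipeline configuration (see `pedconnect check-config`).
# Exactly one of `simulation` / `input` must be present.

simulation:
  n_years: 10
  founders_per_patch: 25
  m_pollen: 0.03
  migrant_fecundity_multiplier: 2.0

# input:
#   genotypes: data/genotypes.csv   # or a .dat file with dialect: franz_dat
#   metadata: data/metadata.tsv
#   dialect: csv

qc:
  max_locus_missing: 0.05
  max_indiv_missing: 0.10

assignment:
  error_rate: 0.01
  posterior_threshold: 0.95
  min_typed_loci: 16
  repro_age_max: 20

popgen:
  n_permutations: 199
  filter_hwe: true
  hwe_alpha: 0.05
  per_year_fst: true

fitness:
  last_years_excluded: 2

output_dir: results/pipeline
seed: 1
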