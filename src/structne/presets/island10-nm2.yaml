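deme_sizes:
- 500
- 500
- 500
- 500
- 500
- 500
- 500
- 500
- 500
- 500
events: []
family: reciprocal_migration
genome:
  map_rate: 1.0e-08
  mutation_rate: 2.0e-09
  n_chromosomes: 20
  sequence_length_bp: 250000000
migration_period: 1
migration_rate: 0.004
name: island10-nm2
sample:
  focal_deme: 0
  scheme: pooled_equal
  total_sample: 100
seed: 0
total_generations: 10000
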