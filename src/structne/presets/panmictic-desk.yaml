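deme_sizes:
- 200
events: []
family: panmictic
genome:
  map_rate: 5.0e-08
  mutation_rate: 1.0e-08
  n_chromosomes: 4
  sequence_length_bp: 10000000
migration_period: 1
migration_rate: 0.0
name: panmictic-desk
sample:
  focal_deme: 0
  scheme: single_deme
  total_sample: 100
seed: 0
total_generations: 2000
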