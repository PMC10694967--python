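deme_sizes:
- 100
events:
- daughter_sizes:
  - 100
  - 100
  kind: split
  time: 100
- kind: admix
  size: 10
  time: 1
family: synthetic
genome:
  map_rate: 1.0e-07
  mutation_rate: 2.0e-08
  n_chromosomes: 4
  sequence_length_bp: 10000000
migration_period: 1
migration_rate: 0.0
name: synthetic-2pop-n100-t5-desk
sample:
  focal_deme: 0
  scheme: single_deme
  total_sample: 100
seed: 0
total_generations: 1000
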