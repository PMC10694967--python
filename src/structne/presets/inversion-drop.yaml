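deme_sizes:
- 1000
events:
- deme: 0
  kind: resize
  size: 100
  time: 10
family: inversion
genome:
  map_rate: 1.0e-08
  mutation_rate: 2.0e-09
  n_chromosomes: 20
  sequence_length_bp: 250000000
inversion:
  end_bp: 150000000
  initial_copies: 1
  introduce_time: 50
  selection_coefficient: 0.2
  start_bp: 100000000
  target_mode: balanced
migration_period: 1
migration_rate: 0.0
name: inversion-drop
sample:
  focal_deme: 0
  scheme: single_deme
  total_sample: 100
seed: 0
total_generations: 10000
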