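deme_sizes:
- 100
events:
- deme: 0
  kind: resize
  size: 10
  time: 1
family: inversion
genome:
  map_rate: 1.0e-07
  mutation_rate: 2.0e-08
  n_chromosomes: 4
  sequence_length_bp: 10000000
inversion:
  end_bp: 6000000
  initial_copies: 1
  introduce_time: 5
  selection_coefficient: 1.9
  start_bp: 4000000
  target_mode: balanced
migration_period: 1
migration_rate: 0.0
name: inversion-drop-desk
sample:
  focal_deme: 0
  scheme: single_deme
  total_sample: 100
seed: 0
total_generations: 1000
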