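deme_sizes:
- 1000
- 100
events:
- deme: 1
  kind: resize
  size: 10
  time: 1
family: source_sink
genome:
  map_rate: 1.0e-07
  mutation_rate: 2.0e-08
  n_chromosomes: 4
  sequence_length_bp: 10000000
migration_period: 1
migration_rate: 0.1
name: source-sink-decline-desk
sample:
  focal_deme: 1
  scheme: single_deme
  total_sample: 100
seed: 0
total_generations: 1000
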