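# Demo run: a scaled-down corpus and network sizing that exercises the whole
# pipeline end to end in a couple of minutes on one CPU.  Study-scale values
# (300-d embeddings, 1000-token sequences, full 8/16 x 0.5/0.7 grid) are the
# library defaults; override the sections below to use them.
outdir: otitext_demo
seed: 7
verbosity: 1

generator:
  n_visits: 2600
  n_pediatricians: 15
  male_fraction: 0.522
  negation_rate: 0.05
  other_doctor_rate: 0.05
  atypical_term_rate: 0.2
  typo_rate: 0.1
  date_range: [2004-01-01, 2012-12-31]

preprocess:
  max_length: 64

embedding:
  dimension: 16
  window: 3
  epochs: 2

split:
  set_sizes: {train: 800, validation: 400, test: 400}
  min_records_per_set: 400
  historical_cutoff: 2008-01-01

train:
  architectures: [0, 1, 2, 3, 4]
  filters: 12
  batch_sizes: [8]
  hidden_dropouts: [0.5]
  learning_rate: 0.003
  max_epochs: 10
  patience: 3
  n_transfer: 200
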