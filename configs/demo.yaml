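# Demo pipeline configuration: a 2000-patient synthetic EMR analysed with
# the full topic grid. Runs end to end on one CPU in a few minutes.
seed: 1
generator:
  n_patients: 2000
  n_providers: 250
  doc_length_mean: 80.0
lda:
  n_iterations: 400
  n_burnin: 100
model:
  k_grid: [0, 5, 10, 15, 20]
  n_folds: 10
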