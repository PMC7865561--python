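# Demo: a scaled-down synthetic study, end-to-end in ~1 minute.
#   bagpipe run --config examples/demo.yaml --out demo_out
seed: 1
synthetic: true
out_dir: demo_out
synthetic_overrides:
  n_train: 200
  n_patient: 80
  n_features_t1: 40
  n_features_dti: 48
  bag_shift: 3.0
cv_reps: 10
analyses: [bag]
q: 0.1
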