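# Demo pipeline: a 300-screening cohort with NDI-only examiner errors.
# Run with:  polyverify run --config configs/demo.yaml --out artifacts/
simulation:
  n_screenings: 300
  effect_size: 1.5
  deception_prevalence: 0.06
  examiner_error_rate: 0.05
  error_mode: ndi_only
  seed: 7
featurize:
  post_answer_s: 5.0
model:
  variant: universal
  anchor_topic: drug_abuse
evaluation:
  max_fpr: 0.05
flagging:
  top_fraction: 0.05
io:
  write_screenings: false
  write_features: true
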