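# Full-pipeline configuration for `sedcm run --config examples/full_run.yaml`.
# Every stage seed is derived from the master seed; omitted settings use
# packaged defaults (paper-shaped cohort, default effect structure,
# 25-Hz probe, log(2) transition threshold).
seed: 7
out_dir: sedcm_demo_run

cohort:
  n_responders: 8
  n_nonresponders: 9
  between_patient_sd: 0.05
  noise_sd: 0.1
  output: spectra

inversion:
  max_iter: 128
  tol_nats: 0.01

probe_freq: 25.0
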