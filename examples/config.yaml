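# Full-grid evaluation on a small synthetic cohort.
seed: 42
output_dir: ppgcvd_out
cohort:
  n_cvd: 4
  n_normal: 4
  duration: 60.0          # seconds per subject
  morphology_shift: 0.5   # class separability in [0, 1]
methods: [HT, NLR, ABC_PSO, CUCKOO, DRAGONFLY]
classifiers: [PCA, EM, LOGREG, GMM, BLDC, FIREFLY, HARMONY, DFA,
              PAC_BAYES, KNN_PAC, SDC, DETREND_SDC]
folds:
  n_folds: 10
  subject_level: false    # segment-level stratified folds (study protocol)
coding:
  t_cvd: 0.85
  t_normal: 0.1
stop:
  mse_tol: 1.0e-5
  max_iter: 1000
swarm:
  pop_size: 20
  max_iter: 30
denoise: false
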