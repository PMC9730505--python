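# Demo configuration for `tcemm run-all --config examples/config.yaml`
seed: 1
output_dir: tcemm_out

registry:
  fasta: null            # path to an allele FASTA, or null to synthesize
  version_tag: synthetic-1
  n_alleles_per_locus: 6
  n_polymorphic_sites: 14

pool:
  n_haplotypes: 12
  concentration: 1.0

engine:
  q_bind: 0.2
  scoring: distinct_core          # or core_presenter
  self_repertoire_binding_filtered: false

cohort:
  n_pairs: 2000
  admin_censor_time: 15.0
  weibull_sigma: 0.8
  target_event_fraction: 0.17
  random_censor_rate: 0.025
  n_planted: 5
  planted_beta: -0.5
  planted_min_support: 50

screen:
  min_support: 50
  alpha: 0.05
  ph_test_on: significant         # none | significant | all

selection:
  n_folds: 10
  posi_method: split              # split | naive
  n_alphas: 50

network:
  beta: 4.0
  adjacency_threshold: 0.3

logo:
  n_perm: 1000
  comparison: lasso_selected      # lasso_selected | posi_significant

version_diff:
  enabled: true
  n_edits: 2
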