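# Demo pipeline configuration: simulate a registry-like cohort and run the
# full analysis. Paths are omitted, so a synthetic cohort is generated.
seed: 11
n_patients: 3000
out_dir: bcmort_demo
horizon: 10.0
age_adjust_table3: continuous
age_adjust_table4: categorical
smr_spec:
  iterations: 5000
  burn_in: 2000
  chains: 4
  pooling_mode: per_cause_sigma
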