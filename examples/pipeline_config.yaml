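# End-to-end pipeline configuration for `trajclust run`.
# Generate an input cohort first, e.g.:
#   trajclust simulate --subjects-per-component 12 --seed 1 --out cohort.csv
input_csv: cohort.csv
output_dir: pipeline_out
# null -> the default health schema (heart_disease/diabetes/stroke + bmi/smoking)
schema: null
select_states: true
s_range: [2, 3]
k_range: [2, 3, 4, 5, 6]
distance_method: empirical
pam_restarts: 5
em:
  n_restarts: 5
  tol: 1.0e-6
mds_dims: 3
seed: 1
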