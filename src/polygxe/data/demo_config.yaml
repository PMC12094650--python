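# Demonstration pipeline configuration: a desk-scale synthetic study with
# the default cohort design (717 cases / 356 controls, K = 1%).
master_seed: 20260921
output_dir: scratch/demo_run
log_level: INFO
simulation:
  M: 800
  n_ref: 1500
  block_size: 40
  rho: [0.2, 0.9]
  h2: 0.3
  p_causal: 0.03
  N_gwas: 50000
  K: 0.01
  n_case: 717
  n_control: 356
prs:
  n_iter: 300
  burn_in: 60
power:
  n_reps: 200
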