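# Minimal end-to-end demonstration on synthetic data.
seed: 7
output_dir: results/quickstart
subjects: 2
TR: 2.0
n_permutations: 200
connectome:
  source: synthetic
  n_regions: 16
  density: 0.4
tables:
  mu_step: 0.25
  sigma_min: 0.25
  sigma_max: 3.5
  sigma_step: 0.25
global:
  duration: 12.0
  transient: 2.0
perturbations:
  - family: global_coupling
    scales: [1.0, 0.8]
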