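# Full synthetic-world pipeline run: `earmorph run --config examples/pipeline.yaml`
synthetic:
  n_species: 33
  specimens_per_species: 2
  root_age: 75.0
  landmark_noise_sd: 0.01
  audiogram_noise_sd: 1.0
n_perm: 999
seed: 1
outdir: results/example_run
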