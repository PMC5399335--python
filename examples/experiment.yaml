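# Full-experiment configuration for `ovinepred run --config examples/experiment.yaml`.
# Any PopulationConfig / QCThresholds field can be set; unset fields keep their
# documented defaults.
simulation:
  n_snps_dense: 4000
  n_reference: 800
  n_founders_per_breed: 100
  divergence_generations: 30
  n_qtl: 300
  n_validation_sires_per_breed: 8
  h2_target: 0.3
  seed: 31
panels: [moderate, dense]
methods: [GBLUP]
reference_definition: all
run_pblup: false
output_dir: scratch/experiment_from_yaml
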