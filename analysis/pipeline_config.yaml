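# Full study-replication pipeline at the published cohort composition.
# `twinace run --config analysis/pipeline_config.yaml`
seed: 2023
out_dir: results/pipeline
simulate: true
univariate_trait: synaesthesia
bivariate_traits: [total_autistic_traits, rrbid, sic]
prepare: true
sensitivity: true
alpha: 0.05
model_family: AE
sex_effect: 0.15
year_effect: 0.02
missing_rate: 0.02
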