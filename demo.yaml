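# Demo pipeline configuration: the default synthetic sputum cohort
# (asthma / COPD / control, n = 10 per group, 2000 features per modality,
# cohort cell-fraction and RIN distributions, spiked group effects).
seed: 17
out_dir: demo_out
scenario: {}            # empty -> ScenarioConfig defaults
comparison: [asthma, control]
excluded: [MO]
bounds_mode: auto
rin_mode: linear
min_rin: 3.0
policy: paper
max_gap: 1000
min_cpgs: 2
min_overlap: 200
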