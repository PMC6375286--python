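# Demo pipeline configuration: one colony, single YFP reporter, 8-step chain.
# Run: stresstiming run --config examples/demo_config.toml --out results/demo --seed 3

[simulate]
n_founders = 10
growth_rate_mean = 0.35      # 1/h
growth_rate_sd = 0.03
pre_stress_duration = 1.0    # h before stress addition (time zero)
post_stress_duration = 8.0   # h of imaging after stress
frame_interval = 0.1667      # 10-minute frames
lineage_jitter_sd = 0.02     # h, inheritance jitter per division

[simulate.chain]
type = "single"              # or "serial" / "parallel" with two reporters
n_steps = 8
mean_time = 3.0              # h

[simulate.reporters.yfp]
production_rate = 100.0
maturation_time = 0.1667     # ~10 min
decay_rate = 3.0             # 1/h, sets the observable rise rate
bleach_per_frame = 0.03
autofluorescence = 2.0
noise_sd = 0.3

[simulate.background]
yfp = 1.5                    # per-pixel background outside cells

[preprocess]
background_mode = "per_frame"

[preprocess.autofluorescence]
yfp = 2.0

[response]
threshold_fraction = 0.25
responder_fold = 3.0

[stats]
n_subsamples = 1000
n_bootstrap = 500
n_permutations = 1000

[kinetics]
ks_sims = 1000
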