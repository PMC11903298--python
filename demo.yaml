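# One-command demonstration: synthetic tile scenes for 2017-2023, twelve
# plantations, an injected post-2018 palm-coverage decline, full pipeline
# through the panel models. Run:  palmwatch run --config demo.yaml
seed: 7
output_dir: palmwatch_out
years: [2017, 2018, 2019, 2020, 2021, 2022, 2023]
reference_year: 2018

scene_width: 120
scene_height: 120
cloud_fraction: 0.2
noise_sd: 0.015
n_captures: 3
palm_decline_per_year: 0.03

n_plantations: 12

tau: 0.12
window_days: 15

k: 8
kmeans_sample_size: 20000

coverage_mode: mature_plus_immature
year_dummies: true
log_level: INFO
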