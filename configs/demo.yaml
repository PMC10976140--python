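# Demo run: 35-site network, two simulated years + long-term mean,
# all three model families with and without ordinary kriging.
pollutant: NO2
site_subset: all
families: [PLS, RF, SLR]
kriging: true
seed: 0
output_dir: lurok_demo_run
n_sites: 35
n_years: 2
start_year: 2015
n_variables: 12
n_signal: 4
missing_rate: 0.15
residual_sill: 9.0
residual_range: 15000.0
nugget: 0.25
noise_sd: 8.0
seasonal_amplitude: 10.0
pls_n_scores: 3
rf_mtry: 50
rf_ntree: 500
rf_node_size: 5
slr_r2_gain: 0.1
slr_vif_max: 3.0
slr_enforce_sign: true
variogram_family: exponential
utc_offset_hours: 8
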