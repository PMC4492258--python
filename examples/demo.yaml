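# Demo study region: Los Angeles-like network layout with method
# distortions on the regulatory networks (multiplicative bias standing in
# for a different carbon protocol, extra day-to-day variability of 24-hr
# samples). Run with:
#   monitorharm run-all --config examples/demo.yaml --outdir demo_out
seed: 1
region_preset: los_angeles
n_periods: 40
anchor_wednesday: "2007-03-07"
pollutant: EC
gamma0: [0.5, 0.3, 0.0]
gamma1: [1.5, 0.0, 0.2]
resid_sill: 0.04
resid_range_km: 10.0
nugget: 0.01
distortions:
  CSN_CORE: {mult_bias: 0.8, noise_cv: 0.3, daily_cv: 0.5}
  CSN_SUPP: {mult_bias: 0.8, noise_cv: 0.3, daily_cv: 0.5}
  IMPROVE: {mult_bias: 0.9, noise_cv: 0.3, daily_cv: 0.5}
amplitude_mode: constant
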