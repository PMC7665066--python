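# Four-region demonstration study: two unimodal (Musumi) and two bimodal
# (Vuli + Masika) regions, harvest years 2010-2019, ground-truth yields
# driven by extreme-rain days (vegetative) and cold snaps (reproductive).
seed: 42

synthetic:
  n_regions: 4
  n_grid_cells_per_region: 2
  years: [2010, 2019]
  regime_per_region: [unimodal, bimodal, unimodal, bimodal]
  mean_annual_rain: 900.0

truth:
  features: [precip.p99_v, tas.min01_r]
  betas: [0.7, -0.6]
  trend_type: linear
  trend_coefficients: [0.47, 0.01]
  noise_sd: 0.05

gdd: {t_base: 10.0, t_cap: 30.0}

onset_windows:
  unimodal: [305, 59]   # 1 Nov (previous year) .. 28 Feb
  bimodal: [32, 120]    # 1 Feb .. 30 Apr (Masika onset)

leads: {nino34: 120, wp: 120, iod: 30}

caps: {estimation: 5, level2: 4}
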