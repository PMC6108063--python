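# Default synthetic survey spec for the Choke Mountain study area.
# Per-unit sample sizes and the proportions/means of the published summary
# tables are used where available; within-unit dispersions and the remaining
# parameters are synthetic conventions (flagged "invented" below).
seed: 2012
units:
  - {id: AES1, n: 87}
  - {id: AES2, n: 183}
  - {id: AES3, n: 148}
  - {id: AES4, n: 284}
  - {id: AES5, n: 91}

categorical:
  temperature_perception:
    categories: [increasing, decreasing, no_change, dont_know]
    probs:
      AES1: [0.952, 0.024, 0.024, 0.000]
      AES2: [0.783, 0.141, 0.016, 0.054]
      AES3: [0.946, 0.034, 0.007, 0.014]
      AES4: [0.796, 0.186, 0.009, 0.000]
      AES5: [0.802, 0.121, 0.033, 0.044]
  precipitation_perception:
    categories: [increasing, decreasing, no_change, seasonality, drought, dont_know]
    probs:
      AES1: [0.083, 0.655, 0.048, 0.107, 0.095, 0.012]
      AES2: [0.130, 0.560, 0.016, 0.234, 0.038, 0.011]
      AES3: [0.027, 0.547, 0.014, 0.311, 0.074, 0.027]
      AES4: [0.009, 0.699, 0.018, 0.230, 0.035, 0.009]
      AES5: [0.055, 0.604, 0.011, 0.275, 0.033, 0.022]
  extreme_event:
    categories: ["yes", "no"]
    probs:
      AES1: [0.783, 0.217]
      AES2: [0.850, 0.150]
      AES3: [0.583, 0.417]
      AES4: [0.857, 0.143]
      AES5: [0.690, 0.310]
  swc:
    categories: ["yes", "no"]
    probs:
      AES1: [0.464, 0.536]
      AES2: [0.250, 0.750]
      AES3: [0.378, 0.622]
      AES4: [0.360, 0.640]
      AES5: [0.363, 0.637]
  land_productivity:
    categories: [increased, decreased, no_change]
    probs:
      AES1: [0.395, 0.556, 0.049]
      AES2: [0.376, 0.594, 0.029]
      AES3: [0.320, 0.633, 0.036]
      AES4: [0.243, 0.621, 0.067]
      AES5: [0.180, 0.753, 0.067]
  land_ownership:
    categories: ["yes", "no"]
    probs:
      AES1: [0.952, 0.048]
      AES2: [0.913, 0.087]
      AES3: [0.973, 0.027]
      AES4: [0.937, 0.063]
      AES5: [0.956, 0.044]
  farmland_change:
    categories: [increased, decreased, no_change]
    probs:
      AES1: [0.111, 0.580, 0.309]
      AES2: [0.040, 0.525, 0.435]
      AES3: [0.116, 0.363, 0.521]
      AES4: [0.126, 0.550, 0.324]
      AES5: [0.100, 0.611, 0.289]
  gender:
    categories: [male, female]
    probs: {default: [0.933, 0.067]}
  literate:
    categories: ["yes", "no"]
    probs: {default: [0.549, 0.451]}
  extension:
    categories: ["yes", "no"]
    probs: {default: [0.990, 0.010]}
  fertilizer:
    categories: ["yes", "no"]
    probs:
      AES1: [0.640, 0.360]
      AES2: [0.850, 0.150]
      AES3: [0.850, 0.150]
      AES4: [0.850, 0.150]
      AES5: [0.500, 0.500]
  improved_seed:
    categories: ["yes", "no"]
    probs:
      AES1: [0.190, 0.810]
      AES2: [0.220, 0.780]
      AES3: [0.100, 0.900]
      AES4: [0.200, 0.800]
      AES5: [0.040, 0.960]
  irrigation:
    categories: ["yes", "no"]
    probs:
      AES1: [0.180, 0.820]
      AES2: [0.100, 0.900]
      AES3: [0.250, 0.750]
      AES4: [0.240, 0.760]
      AES5: [0.220, 0.780]
  insecticide:  # invented per-unit levels
    categories: ["yes", "no"]
    probs:
      AES1: [0.250, 0.750]
      AES2: [0.350, 0.650]
      AES3: [0.300, 0.700]
      AES4: [0.320, 0.680]
      AES5: [0.200, 0.800]
  credit:
    categories: ["yes", "no"]
    probs: {default: [0.850, 0.150]}
  electricity:
    categories: ["yes", "no"]
    probs: {default: [0.420, 0.580]}
  telephone:
    categories: ["yes", "no"]
    probs: {default: [0.650, 0.350]}
  radio:  # invented
    categories: ["yes", "no"]
    probs: {default: [0.550, 0.450]}
  cbo:  # invented
    categories: ["yes", "no"]
    probs: {default: [0.700, 0.300]}
  bylaws:  # invented
    categories: ["yes", "no"]
    probs: {default: [0.800, 0.200]}
  worktogether:  # invented
    categories: ["yes", "no"]
    probs: {default: [0.900, 0.100]}

numeric:
  land_ha:
    dist: lognormal
    cv: 0.5
    mean: {AES1: 1.00, AES2: 0.97, AES3: 1.23, AES4: 1.28, AES5: 1.10}
  savings_birr:  # invented levels (midlands wealthier)
    dist: lognormal
    cv: 0.8
    mean: {AES1: 800, AES2: 2000, AES3: 2200, AES4: 1800, AES5: 700}
  loan_birr:  # invented
    dist: lognormal
    cv: 0.8
    mean: {AES1: 900, AES2: 1200, AES3: 1100, AES4: 1300, AES5: 800}
  offfarm_income_birr:  # invented
    dist: lognormal
    cv: 0.8
    mean: {AES1: 1200, AES2: 1500, AES3: 1600, AES4: 1400, AES5: 1000}
  production_t:  # invented (midlands more productive)
    dist: lognormal
    cv: 0.5
    mean: {AES1: 1.2, AES2: 2.5, AES3: 2.4, AES4: 1.8, AES5: 1.0}
  yield_t_ha:  # invented
    dist: lognormal
    cv: 0.4
    mean: {AES1: 1.0, AES2: 1.8, AES3: 1.9, AES4: 1.4, AES5: 0.8}
  crop_count:  # invented
    dist: lognormal
    cv: 0.3
    mean: {AES1: 3.0, AES2: 5.0, AES3: 5.0, AES4: 4.0, AES5: 3.0}
  road_hours:  # invented (hours walking)
    dist: lognormal
    cv: 0.4
    mean: {AES1: 1.5, AES2: 1.2, AES3: 1.3, AES4: 1.4, AES5: 2.0}
  school_hours:  # invented
    dist: lognormal
    cv: 0.4
    mean: {AES1: 0.9, AES2: 0.8, AES3: 0.8, AES4: 0.9, AES5: 1.1}
  vet_hours:  # invented
    dist: lognormal
    cv: 0.4
    mean: {AES1: 1.0, AES2: 0.9, AES3: 0.9, AES4: 1.0, AES5: 1.4}
  market_hours:  # invented
    dist: lognormal
    cv: 0.4
    mean: {AES1: 1.3, AES2: 1.0, AES3: 1.0, AES4: 1.2, AES5: 1.8}
  health_hours:  # invented
    dist: lognormal
    cv: 0.4
    mean: {AES1: 0.8, AES2: 0.7, AES3: 0.7, AES4: 0.8, AES5: 1.2}
  trainings_attended:  # invented
    dist: lognormal
    cv: 0.6
    mean: {AES1: 1.0, AES2: 1.5, AES3: 1.5, AES4: 1.2, AES5: 0.8}
  governance_score:  # invented (1-5 scale)
    dist: normal
    mean: {default: 3.5}
    sd: {default: 0.8}
  participation_index:  # invented
    dist: lognormal
    cv: 0.5
    mean: {default: 0.5}
  nonworking_days:  # invented (days/month)
    dist: lognormal
    cv: 0.3
    mean: {AES1: 4.5, AES2: 4.0, AES3: 4.0, AES4: 4.2, AES5: 5.0}

livestock:
  # herd composition is an invented convention; rates are scaled so the
  # expected TLU matches the published per-unit means
  composition: {cattle: 2.0, sheep: 2.0, goat: 1.0, donkey: 0.5, chicken: 3.0}
  tlu_mean: {AES1: 1.26, AES2: 1.56, AES3: 1.13, AES4: 2.16, AES5: 1.45}

climate:
  # stand-ins for the three station temperature records (~0.3 degC/decade)
  # and one precipitation record with no trend; baselines/sds invented
  - {series_id: lowland_tmax, start_year: 1990, n_years: 23, slope: 0.03, sd: 0.50, baseline: 29.0, units: degC}
  - {series_id: midland_tmax, start_year: 1982, n_years: 31, slope: 0.03, sd: 0.35, baseline: 25.0, units: degC}
  - {series_id: highland_tmax, start_year: 1982, n_years: 31, slope: 0.03, sd: 0.40, baseline: 18.0, units: degC}
  - {series_id: midland_precip, start_year: 1982, n_years: 31, slope: 0.0, sd: 120.0, baseline: 1300.0, units: mm}
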