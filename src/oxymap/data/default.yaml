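# Default study configuration.
#
# Units: w in m/day, kappa in m^2/s, a in 1/day; temperatures in degC;
# oxygen in mmol/m^3; depths in m.  Priors are independent Gaussians
# specified by mean and relative standard deviation, truncated from
# below at `floor` (if omitted, 5% of the mean).

parameters:
  w:     {mean: 15.0,   rel_sd: 0.5,  floor: 0.75}
  kappa: {mean: 3.0e-5, rel_sd: 0.5,  floor: 1.5e-6}
  a:     {mean: 0.6,    rel_sd: 0.25, floor: 0.03}

quadrature:
  points_per_dim: 5   # 5^3 = 125 ensemble members
  max_order: 3        # third-order Hermite basis (20 terms)

ocean:
  grid: {depth: 1000.0, dz: 10.0}
  constants: {s0: 350.0, s1: 6.0, f_max: 40.0, k_a: 0.3, r: 0.1}
  n_columns: 100
  seed: 0
  # regimes omitted -> built-in defaults (deep_water_formation /
  # tropical_omz / intermediate at fractions 0.2 / 0.4 / 0.4)

# regions omitted -> one region per regime, selected by regime label

diagnostics:
  eps: 1.0e-6          # mmol/m^3 guard on ratio denominators
  mask_threshold: 0.06 # mask where ensemble sd < 6% of local mean
  weighted: true       # quadrature-weighted ensemble statistics
  spread_quantile: 0.5 # benchmark eligibility: spread above the median
  top_k: 5
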