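# Transition rules of the manufacturer's monthly-cycle Markov cohort model.
# - progression -> death: constant monthly probability, both arms, derived
#   from the inverse of the restricted KM mean of post-progression survival
#   (24.1791 months): p = 1 - exp(-1/24.1791) = 0.0405.
# - progression-free -> death: observed monthly probability per arm, or the
#   age-specific background mortality if larger (life table supplied by the
#   user; off by default).
# - staying progression-free: monthly conditional survival from the same
#   Weibull progression-free-survival regression as the partitioned model.
post_progression_km_mean_months: 24.1791
p_prog_death_monthly: 0.0405
p_pf_death_monthly: {rfc: 0.0012, fc: 0.00139}
pfs_model:
  family: weibull
  params: {log_scale: 1.237, log_shape: 0.310}
  coefficients: {treatment: -0.519}
cohort_start_age: 61.0
horizon: 15.0
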