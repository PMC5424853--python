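# Partitioned-survival regression results for the two-arm CLL trial
# (RFC = rituximab + fludarabine + cyclophosphamide, treatment = 1;
#  FC = fludarabine + cyclophosphamide, treatment = 0).  Time in years.
pfs:
  # Weibull fit to progression-free survival (event: progression or death),
  # whole observed curve, extrapolated over the full horizon.
  family: weibull
  params: {log_scale: 1.237, log_shape: 0.310}
  coefficients: {treatment: -0.519}
  standard_errors: {treatment: 0.117}
os_observed:
  # Exponential fit to overall survival over the observed period.
  family: exponential
  params: {log_scale: 2.753}
  coefficients: {treatment: -0.284}
  standard_errors: {treatment: 0.204}
os_tail:
  # Weibull tail for the FC arm beyond the observed period, from the
  # linearization log(-log S) = a + b log t (a = log_rate, b = shape),
  # evaluated at absolute study time.
  family: weibull_tail
  params: {log_rate: -4.377, shape: 2.257}
observed_boundary: 3.6       # years; junction between observed fit and tail
os_observed_hr: 0.753        # exp(-0.284): maps the FC tail onto the RFC arm
horizon: 15.0
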