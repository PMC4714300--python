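"""Super-annual periodicity: wavelet detection and the SEIR period law.

Simulate an endemic disease, measure its dominant multi-year cycle with the
Morlet wavelet, compare against T = 2*pi*sqrt(A*(D+D')), and invert the
relation the way the KD bound D+D' > 1.1 years is obtained from T > 10 y.
"""

import numpy as np

from kdepi import (
    SEIRConfig,
    dominant_period,
    invert_T,
    morlet_cwt,
    normalize_to_max,
    predict_T,
    simulate_seir,
    weekly_to_monthly,
)

cfg = SEIRConfig(
    n_regions=1, population=5e5, r0=80.0 / 4.0,      # mean infection age ~4 y
    incubation_years=0.03, infectious_years=0.07,    # D + D' = 0.1 y
    seasonal_amplitude=0.05, burn_in_years=10, record_years=40,
    import_rate=2e-4, fertility_scale=np.array([1.0]), seed=5,
)
bundle = simulate_seir(cfg)

monthly = normalize_to_max(weekly_to_monthly(bundle.weekly["pooled"]))
result = morlet_cwt(monthly)
t_measured = dominant_period(result, min_period_months=18.0)

a = float(bundle.truth["realized_mean_infection_age"].iloc[0])
t_predicted = predict_T(a, cfg.incubation_years, cfg.infectious_years)

print(f"realized mean infection age A = {a:.2f} y")
print(f"wavelet dominant period       = {t_measured:.2f} y")
print(f"2*pi*sqrt(A*(D+D'))           = {t_predicted:.2f} y")
print(f"inverting T=10 y at A=2.4 y   => D+D' = {invert_T(10.0, 2.4):.2f} y")
print("=> the observed multi-year cycle matches the theoretical "
      "inter-epidemic period; a 10-year cycle at KD's mean age implies a "
      "combined incubation + infectious duration above one year.")
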