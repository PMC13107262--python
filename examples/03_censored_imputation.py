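"""Right-censored (Tobit) modelling and stochastic tail imputation.

Draws activity values from a known Gaussian, censors them at the tag
ceiling (3.43 m/s^2), refits the censored-Gaussian model, and imputes
the ceiling values from the fitted upper tail.
"""

import numpy as np
from scipy import stats

from codactivity import fit_tobit, impute_censored

rng = np.random.default_rng(1)
mu, sigma, C, n = 2.8, 0.6, 3.43, 5000
y_true = rng.normal(mu, sigma, n)
y = np.minimum(y_true, C)  # what the tags transmit

fit = fit_tobit(y, np.ones((n, 1)), C)
se = fit.se()
print(f"censored observations: {fit.n_censored} / {n} "
      f"({100 * fit.n_censored / n:.1f}%)")
print(f"recovered mu    = {fit.coefficients[0]:.3f} +- {se[0]:.3f}  (truth {mu})")
print(f"recovered sigma = {fit.sigma:.3f} +- {se[1]:.3f}  (truth {sigma})")
print(f"naive mean of transmitted values = {y.mean():.3f}  (biased low)")

imputed = impute_censored(y, fit, rng, linear_predictor=np.full(n, fit.coefficients[0]))
a = (C - mu) / sigma
tail_mean = mu + sigma * stats.norm.pdf(a) / stats.norm.sf(a)
print(f"mean of imputed ceiling values = {imputed[y >= C].mean():.3f} "
      f"(theoretical E[Y | Y > {C}] = {tail_mean:.3f})")
print(f"mean after imputation = {imputed.mean():.3f}  (truth {y_true.mean():.3f})")
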