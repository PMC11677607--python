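"""Moran's I and maximum-likelihood spatial-lag regression.

A landscape is simulated with true spatial autocorrelation rho = 0.6.  OLS
residuals show positive Moran's I (spatial structure the model missed); the
SAR lag fit recovers rho and leaves residuals indistinguishable from spatial
noise.
"""

import numpy as np
import pandas as pd
import statsmodels.api as sm

import phylospat as ps
from phylospat.simulate import LandscapeScenario

land = ps.simulate_landscape(LandscapeScenario(n_sites=200, rho_true=0.6, seed=1))
dummies = pd.get_dummies(land.env["bedrock"], dtype=float).iloc[:, 1:]
X = pd.concat([land.X_true, dummies], axis=1)

ols = sm.OLS(land.y.to_numpy(), sm.add_constant(X.to_numpy().astype(float))).fit()
mi_ols = ps.morans_i(ols.resid, land.weights)
print(f"OLS residual Moran's I = {mi_ols.I:+.4f} "
      f"(expectation {mi_ols.expected:+.4f}, p = {mi_ols.p_value:.2e})")

fit = ps.fit_sar_lag(land.y, X, land.weights)
print(f"SAR lag: rho_hat = {fit.rho:.3f} (true 0.6), "
      f"AIC = {fit.aic:.2f}, Nagelkerke pseudo-R2 = {fit.pseudo_r2:.3f}")
print(f"SAR residual Moran's I = {fit.resid_moran.I:+.4f} (p = {fit.resid_moran.p_value:.3f})")
print()
print(fit.summary_frame().round(4).to_string(index=False))
print()
print("A significant OLS residual I and a non-significant SAR residual I show")
print("the lag term absorbing the neighbourhood autocorrelation.")
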