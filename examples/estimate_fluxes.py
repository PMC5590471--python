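"""Estimate internal fluxes of a small pathway by GLS.

A imported at a measured rate, converted to B and then to C, which leaves
the cell at a second measured rate.  The balance regression recovers the two
internal conversion fluxes; the ANOVA tells whether the regression is
statistically significant.
"""

import numpy as np
import pandas as pd

from fluxdiag import (MetabolicModel, build_regression, gls_fit, partition,
                      regression_anova)

S = np.array([
    # EX_A  EX_C  R1   R2
    [1.0, 0.0, -1.0, 0.0],   # A: imported, consumed by R1
    [0.0, 0.0, 1.0, -1.0],   # B: intermediate
    [0.0, -1.0, 0.0, 1.0],   # C: produced by R2, exported
])
model = MetabolicModel(["A", "B", "C"], ["EX_A", "EX_C", "R1", "R2"], S,
                       exchange_reaction_ids=["EX_A", "EX_C"])
measurements = pd.DataFrame({
    "reaction_id": ["EX_A", "EX_C"],
    "value": [2.0, 1.9],        # slight imbalance from measurement error
    "sd": [0.1, 0.1],
})

pm = partition(model, measurements)
problem = build_regression(pm)
est = gls_fit(problem)
anova = regression_anova(est, problem)

print("GLS flux estimates (same units as the measured exchange fluxes):")
for rid, flux, se in zip(pm.internal_ids, est.beta_hat, est.standard_errors):
    print(f"  {rid}: {flux:8.4f}  +/- {se:.4f}")
print(f"ANOVA: F = {anova.f_statistic:.4g}, p = {anova.p_value:.3g}")
print("Both conversions run at ~1.95: the balances reconcile the slightly")
print("inconsistent uptake (2.0) and secretion (1.9) measurements, and the")
print("tiny p value marks the regression as statistically significant.")
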