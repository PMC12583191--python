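"""Urinary concentration standardization on a small synthetic batch.

Builds 200 spot-urine measurements with hydration differences, a limit
of detection, a diurnal trend and a batch offset, then runs the
standardization chain: LOD handling -> specific-gravity dilution
correction -> time-of-day residual adjustment -> batch adjustment.
"""

import numpy as np
import pandas as pd

from expomix.standardize import (
    DilutionContext, batch_adjust, handle_lod, residual_time_adjust,
    standardize_dilution,
)

rng = np.random.default_rng(0)
n = 200
true_conc = rng.lognormal(np.log(1.5), 0.8, n)  # ug/L
sg = rng.uniform(1.005, 1.035, n)               # specific gravity
clock = rng.uniform(7, 19, n)                   # sampling hour
batch = np.where(np.arange(n) < n // 2, "b1", "b2")
# dilution scales the observed value; the two batches read 20% apart;
# afternoon samples drift upward
observed = true_conc * (sg - 1.0) / 0.02 * np.exp(0.02 * (clock - 13))
observed[batch == "b2"] *= 1.2
observed[batch == "b1"] /= 1.2

lod = 0.2
samples = pd.DataFrame({
    "analyte": "MnBP",
    "concentration": np.where(observed < lod, np.nan, observed),
    "censored": observed < lod,
    "lod": lod,
})
print(f"{samples['censored'].sum()} of {n} samples below the LOD "
      f"({lod} ug/L)")

(filled,) = handle_lod(samples, method="sqrt2")
ctx = DilutionContext(method="specific_gravity",
                      sg_median=float(np.median(sg)))
corrected = standardize_dilution(filled["concentration"].to_numpy(), sg, ctx)
log_adj = residual_time_adjust(np.log(corrected), clock)
log_adj = batch_adjust(log_adj, batch)
final = np.exp(log_adj)

print(f"geometric mean raw      : {np.exp(np.log(filled['concentration']).mean()):.3f} ug/L")
print(f"geometric mean adjusted : {np.exp(np.log(final).mean()):.3f} ug/L "
      f"(true GM 1.5)")
r = np.corrcoef(np.log(final), clock)[0, 1]
print(f"correlation with sampling hour after adjustment: {r:+.3f} "
      "(dilution, diurnal and batch artefacts removed)")
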