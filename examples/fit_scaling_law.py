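"""Fit the power law S = gamma * V^beta to a synthetic shape table.

Generates condition-averaged cells spanning two decades of volume around a
gamma = 6.24, beta = 2/3 backbone with 5% log-scatter, then fits with the
exponent free and pinned at 2/3, and checks the growth-law S/V prediction.
"""

import numpy as np

from rodshape import SynthSpec, fit_growth_law, fit_power_law, make_population_table
from rodshape.scaling import sv_ratio_prediction

spec = SynthSpec(n_conditions=5, cells_per_condition=200, seed=7)
table = make_population_table(spec)
print(f"synthetic table: {len(table)} rows, volumes "
      f"{table.volume_um3.min():.2f}-{table.volume_um3.max():.1f} um^3")

for mode in ("free", "fixed"):
    fit = fit_power_law(table, mode=mode)
    print(f"{mode:5s} fit: gamma = {fit.gamma:.3f} +- {fit.gamma_se:.3f}, "
          f"exponent = {fit.exponent:.4f} +- {fit.exponent_se:.4f}  (n={fit.n})")

# volume grows exponentially with growth rate (nutrient growth law)
cond = table.groupby("growth_rate_per_h", as_index=False)["volume_um3"].mean()
law = fit_growth_law(cond.to_numpy())
print(f"growth law: V0 = {law.V0:.3f} um^3, alpha = {law.alpha:.3f} h")
for kap in (0.5, 1.0, 2.0):
    sv = sv_ratio_prediction(kap, law)
    print(f"  predicted S/V at k = {kap:.1f}/h: {sv:.3f} um^-1")
print("Interpretation: the free exponent lands on ~2/3 and gamma on the")
print("generating value; S/V falls with growth rate because faster-growing")
print("cells are bigger at the same shape.")
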