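"""Design -> campaign -> Kriging metamodel -> Sobol indices, end to end.

Deliberately small so it runs in well under a minute: 24 design points,
24-plant plots, one seed per point.  A production study would use a few
thousand design points, 110-plant plots and replicated seeds — same calls,
larger numbers.
"""

import numpy as np

from canomix import fit_kriging, lhs_maximin, run_campaign, sobol_indices
from canomix.design import mixture_bounds

bounds, names = mixture_bounds()
design = lhs_maximin(24, bounds, seed=3, dim_names=names, kind="mixture")

table, _ = run_campaign(
    design, climate_config={"n_days": 360, "seed": 1},
    campaign_seed=3, n_plants=24,
)
assert (table["status"] == "ok").all()
print(table[["n_ears", "l_perc", "f_tot"]].describe().loc[["mean", "min", "max"]])

model = fit_kriging(design, table["n_ears"].to_numpy(), seed=3)
print(f"\nmetamodel nugget (simulation noise estimate): {model.nugget:.4f}")

est = sobol_indices(
    lambda x: model.predict(x)[0], bounds,
    n_base=1024, n_rep=5, seed=3, dim_names=names,
).clipped()
top = np.argsort(est.tsi)[::-1][:3]
print("\nthree most influential inputs for N_ears (total-order index):")
for i in top:
    print(f"  {est.dim_names[i]:12s} TSI = {est.tsi[i]:.3f} +- {est.tsi_sd[i]:.3f}")
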