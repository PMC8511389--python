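"""Generate a synthetic daily climate series and summarize it.

The generator produces a sinusoidal annual temperature course with AR(1)
day-to-day noise and a seasonal incident-PAR curve, starting at a late
autumn sowing date so a full wheat season fits in ~360 days.
"""

import numpy as np

from canomix import generate_climate
from canomix.canopy import thermal_time

series = generate_climate(n_days=360, seed=42)
frame = series.to_frame()

print(frame.head())
print(f"\nmean temperature : {frame['temp_c'].mean():.2f} degC")
print(f"PAR range        : {frame['par_mol_m2_d'].min():.1f} - "
      f"{frame['par_mol_m2_d'].max():.1f} mol m-2 d-1")

tt = thermal_time(series)
print(f"season thermal time: {tt[-1]:.0f} degC d "
      f"(maturity needs ~2350, reached on day {int(np.argmax(tt >= 2350))})")
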