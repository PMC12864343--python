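"""Map rEAR_50% for virtual drugs over the kinetic parameter plane.

Sweeps a small grid of dissociation (k_off) and efflux (k_e) rate
constants for virtual substrates with symmetric permeability 300 nm/s
and uniform partition coefficient 300, at 1 uM dose and 1000 uM
reference P-gp.  Fast efflux (large k_e) pushes the expression-activity
relationship towards non-linearity (rEAR_50% -> 100%); fast
dissociation (large k_off, inefficient efflux) pushes it towards
linearity (rEAR_50% -> 50%).
"""

import numpy as np

from pgpear import sweep_rear50

k_offs = np.logspace(2, 7, 4)
k_es = np.logspace(np.log10(0.03), np.log10(30), 4)

sweep = sweep_rear50(k_offs, k_es, dose_grid_um=[1.0], pgp_grid_um=[1000.0])
pivot = sweep.frame.pivot_table(
    index="k_off_per_s", columns="k_e_per_s", values="rEAR_50_pct"
)

print("rEAR_50% (rows: k_off 1/s, columns: k_e 1/s)")
print(pivot.round(1).to_string())
print()
print("reading guide: 50 = linear EAR, 100 = fully non-linear EAR")
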