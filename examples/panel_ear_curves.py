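"""Expression-activity curves for the seven reference P-gp substrates.

Reproduces the standard panel: each drug is dosed at 1 uM apically with
a reference P-gp expression of 1000 uM, expression is varied from 2% to
300% of the reference, and the relative activity rEAR_x% (cumulative
efflux at x% expression divided by that at 100%, times 100) is printed.
A drug whose rEAR_50% stays near 100% barely responds to losing half
its transporter (non-linear EAR); rEAR_50% near 50% means activity
tracks expression one-to-one (linear EAR).
"""

from pgpear import Condition, classify_ear, ear_curve, get_drug, list_drugs

condition = Condition.from_micromolar(dose_um=1.0, pgp_um=1000.0)
fractions = (2, 7, 15, 30, 50, 100, 200, 300)

header = "drug          " + "".join(f"{f:>7g}%" for f in fractions) + "  class"
print(header)
print("-" * len(header))
for name in list_drugs():
    curve = ear_curve(get_drug(name), condition, fractions)
    row = "".join(f"{v:8.0f}" for v in curve.rear)
    print(f"{name:14s}{row}  {classify_ear(curve)}")
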