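"""Do transport properties or P-gp kinetics shape the EAR?

Builds two hybrid drugs: "ampramil" carries amprenavir's P-gp kinetics
(k_on, k_off, k_e) with verapamil's passive transport (permeabilities
and partition coefficients), "veravir" the reverse.  If passive
transport drove the shape of the expression-activity relationship, the
hybrids would follow their transport donor; instead they follow their
kinetics donor, showing that the efflux efficiency k_off/k_e is the
dominant drug property.
"""

from pgpear import (
    Condition,
    compute_rear,
    efflux_efficiency,
    get_drug,
    make_hybrid,
)

condition = Condition.from_micromolar(dose_um=1.0, pgp_um=1000.0)

amprenavir = get_drug("amprenavir")
verapamil = get_drug("verapamil")
ampramil = make_hybrid(amprenavir, verapamil, "ampramil")
veravir = make_hybrid(verapamil, amprenavir, "veravir")

print(f"{'drug':12s} {'k_off/k_e':>10s} {'rEAR_50%':>9s}")
for drug in (amprenavir, ampramil, verapamil, veravir):
    r50 = compute_rear(drug, condition, 50)
    print(f"{drug.name:12s} {efflux_efficiency(drug):10.3g} {r50:9.1f}")

# ampramil stays (at least) as non-linear as amprenavir and veravir as
# linear as verapamil: the kinetic constants, not passive transport,
# set the EAR type.
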