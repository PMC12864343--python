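"""Reference drug parameterizations and virtual/hybrid drug constructors.

The shipped library holds the kinetic and partitioning parameters of
seven well-characterised P-gp substrates, as estimated by Lumen and
colleagues from MDCKII-MDR1 transwell assay data (kinetic constants
fitted to bidirectional time courses; partition coefficients measured
in unilamellar liposomes mimicking leaflet lipid composition).  The
association rate constant is drug-independent, k_on = 1e8 /M/s.

Permeabilities are tabulated here in nm/s, the unit in which they are
reported, and converted to internal dm/s on construction.
"""

from __future__ import annotations

from dataclasses import replace
from types import MappingProxyType
from typing import Mapping

import yaml

from .model import DrugParams

__all__ = [
    "DRUG_LIBRARY",
    "list_drugs",
    "get_drug",
    "make_virtual_drug",
    "make_hybrid",
    "dump_library",
    "load_library",
]

# name: (k_off 1/s, k_e 1/s, P_AC nm/s, P_BC nm/s, K_AO, K_BO, K_IL)
_TABLE: dict[str, tuple[float, float, float, float, float, float, float]] = {
    "amprenavir":   (7e4, 30.0, 350.0, 420.0, 150.0, 200.0, 100.0),
    "digoxin":      (3e4, 3.0,   40.0,  50.0, 100.0, 100.0, 100.0),
    "ketoconazole": (3e4, 0.2,  730.0, 680.0, 400.0, 400.0, 1000.0),
    "loperamide":   (2e4, 0.4,  320.0, 320.0, 300.0, 450.0, 1500.0),
    "quinidine":    (4e3, 3.0,  670.0, 670.0, 100.0, 100.0, 350.0),
    "verapamil":    (2e4, 0.1,  540.0, 580.0, 200.0, 300.0, 650.0),
    "vinblastine":  (5e4, 3.0,   55.0,  90.0, 200.0, 200.0, 200.0),
}


def _build(name: str, row) -> DrugParams:
    k_off, k_e, p_ac, p_bc, k_ao, k_bo, k_il = row
    return DrugParams.from_assay_units(
        name,
        k_off=k_off,
        k_e=k_e,
        P_AC_nm_s=p_ac,
        P_BC_nm_s=p_bc,
        K_AO=k_ao,
        K_BO=k_bo,
        K_IL=k_il,
    )


#: Frozen mapping of the seven reference substrates (lower-case names).
DRUG_LIBRARY: Mapping[str, DrugParams] = MappingProxyType(
    {name: _build(name, row) for name, row in _TABLE.items()}
)


def list_drugs() -> list[str]:
    """Names of the shipped reference substrates."""
    return sorted(DRUG_LIBRARY)


def get_drug(name: str) -> DrugParams:
    """Look up a reference substrate (case-insensitive).

    Raises
    ------
    KeyError
        For unknown names; the message lists the available drugs.
    """
    key = name.strip().lower()
    try:
        return DRUG_LIBRARY[key]
    except KeyError:
        raise KeyError(
            f"unknown drug {name!r}; available: {', '.join(list_drugs())}"
        ) from None


def make_virtual_drug(
    k_off: float,
    k_e: float,
    P_nm_s: float = 300.0,
    K: float = 300.0,
    name: str | None = None,
) -> DrugParams:
    """Virtual substrate with symmetric transport properties.

    Virtual drugs are used to chart how the expression-activity
    relationship depends on the kinetic constants alone: permeability
    is symmetric across both membranes (``P_AC = P_BC = P``), all three
    partition coefficients are equal (``K``), and ``k_on`` is the
    drug-independent default.
    """
    if name is None:
        name = f"virtual(k_off={k_off:g},k_e={k_e:g},P={P_nm_s:g},K={K:g})"
    return DrugParams.from_assay_units(
        name,
        k_off=k_off,
        k_e=k_e,
        P_AC_nm_s=P_nm_s,
        P_BC_nm_s=P_nm_s,
        K_AO=K,
        K_BO=K,
        K_IL=K,
    )


def make_hybrid(
    kinetics_from: DrugParams, transport_from: DrugParams, name: str
) -> DrugParams:
    """Hybrid drug: P-gp kinetics of one drug, transport of another.

    Takes ``k_on``, ``k_off`` and ``k_e`` from ``kinetics_from`` and the
    passive permeabilities and partition coefficients from
    ``transport_from``.  Swapping transport properties between a
    linearly and a non-linearly responding substrate (e.g. "ampramil" =
    amprenavir kinetics with verapamil transport, and "veravir" vice
    versa) isolates the role of the kinetic constants in shaping the
    expression-activity relationship.
    """
    return replace(
        transport_from,
        name=name,
        k_on=kinetics_from.k_on,
        k_off=kinetics_from.k_off,
        k_e=kinetics_from.k_e,
    )


def dump_library(path, library: Mapping[str, DrugParams] | None = None) -> None:
    """Write a drug library to a YAML file (assay units, see README)."""
    if library is None:
        library = DRUG_LIBRARY
    payload = {
        name: {
            "k_on_per_M_s": d.k_on,
            "k_off_per_s": d.k_off,
            "k_e_per_s": d.k_e,
            "P_AC_nm_s": d.P_AC_nm_s,
            "P_BC_nm_s": d.P_BC_nm_s,
            "K_AO": d.K_AO,
            "K_BO": d.K_BO,
            "K_IL": d.K_IL,
        }
        for name, d in library.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_library(path) -> dict[str, DrugParams]:
    """Load a drug library written by :func:`dump_library`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {
        name.lower(): DrugParams.from_assay_units(
            name.lower(),
            k_off=row["k_off_per_s"],
            k_e=row["k_e_per_s"],
            P_AC_nm_s=row["P_AC_nm_s"],
            P_BC_nm_s=row["P_BC_nm_s"],
            K_AO=row["K_AO"],
            K_BO=row["K_BO"],
            K_IL=row["K_IL"],
            k_on=row["k_on_per_M_s"],
        )
        for name, row in payload.items()
    }
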