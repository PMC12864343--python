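"""Core kinetic model of drug disposition in a P-gp transwell assay.

The model describes a confluent monolayer of P-glycoprotein (P-gp)
expressing cells separating an apical and a basolateral chamber, the
standard geometry of an in vitro transwell permeability assay.  Drug
moves by passive diffusion between the three aqueous compartments
(apical chamber, cytoplasm, basolateral chamber), partitions
instantaneously into the membrane leaflets adjacent to each aqueous
phase, binds P-gp from the apical inner leaflet by mass action, and is
either released back into the leaflet or effluxed into the apical
chamber.  A first-order rate constant ``k_v`` accounts for unexplained
loss from the system.

State variables (all molar except the two amounts):

==============  =====================================================
``C_AC``        drug concentration in the apical chamber (M)
``C_CP``        drug concentration in the cytoplasm (M)
``C_BC``        drug concentration in the basolateral chamber (M)
``C_Pgp_free``  free P-gp concentration (M)
``C_Pgp_bound`` drug-bound P-gp concentration (M)
``A_eff_cum``   cumulative amount effluxed by P-gp (mol)
``A_loss_cum``  cumulative amount removed by ``k_v`` (mol)
==============  =====================================================

The two cumulative amounts are quadrature states: their time
derivatives are the instantaneous efflux rate ``k_e * C_Pgp_bound *
0.5 * V_IL`` and the instantaneous loss rate, so the integrator itself
evaluates the time integrals and the read-outs do not depend on the
output grid.

Internal unit convention: dm, dm^2, dm^3, s, mol/L (M).  Permeabilities
are commonly tabulated in nm/s (1 nm/s = 1e-8 dm/s) and concentrations
quoted in uM (1 uM = 1e-6 M); conversion helpers are provided at the
boundaries (`DrugParams.from_assay_units`, `Condition.from_micromolar`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "NM_PER_S",
    "MICROMOLAR",
    "DrugParams",
    "SystemParams",
    "Condition",
    "EffectiveVolumes",
    "State",
    "effective_volumes",
    "initial_state",
    "leaflet_concentrations",
    "rhs",
]

#: dm/s per nm/s.
NM_PER_S = 1e-8
#: M per uM.
MICROMOLAR = 1e-6

#: Drug-independent P-gp association rate constant (1/M/s).
DEFAULT_K_ON = 1e8


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class DrugParams:
    """Kinetic and partitioning parameters of one P-gp substrate.

    All values are in internal units (permeabilities in dm/s).  Use
    :meth:`from_assay_units` to construct from the units in which these
    parameters are usually reported (permeabilities in nm/s).

    Parameters
    ----------
    name
        Drug label.
    k_on
        P-gp association rate constant (1/M/s); drug-independent in
        this model, default 1e8.
    k_off
        P-gp dissociation rate constant (1/s).
    k_e
        P-gp efflux rate constant (1/s).  ``k_e = 0`` is permitted for
        null-efflux controls.
    P_AC, P_BC
        Passive permeabilities across the apical / basolateral
        membrane (dm/s).  Diffusion is symmetric: the same coefficient
        applies in both directions across a given membrane.
    K_AO, K_BO, K_IL
        Dimensionless partition coefficients into the apical outer
        leaflet, basolateral outer leaflet and the inner leaflets.
    """

    name: str
    k_off: float
    k_e: float
    P_AC: float
    P_BC: float
    K_AO: float
    K_BO: float
    K_IL: float
    k_on: float = DEFAULT_K_ON

    def __post_init__(self) -> None:
        _require(self.k_on > 0, "k_on must be > 0")
        _require(self.k_off > 0, "k_off must be > 0")
        _require(self.k_e >= 0, "k_e must be >= 0")
        _require(self.P_AC > 0 and self.P_BC > 0, "permeabilities must be > 0")
        _require(
            self.K_AO > 0 and self.K_BO > 0 and self.K_IL > 0,
            "partition coefficients must be > 0",
        )

    @classmethod
    def from_assay_units(
        cls,
        name: str,
        *,
        k_off: float,
        k_e: float,
        P_AC_nm_s: float,
        P_BC_nm_s: float,
        K_AO: float,
        K_BO: float,
        K_IL: float,
        k_on: float = DEFAULT_K_ON,
    ) -> "DrugParams":
        """Build from permeabilities in nm/s (1 nm/s = 1e-8 dm/s)."""
        return cls(
            name=name,
            k_off=k_off,
            k_e=k_e,
            P_AC=P_AC_nm_s * NM_PER_S,
            P_BC=P_BC_nm_s * NM_PER_S,
            K_AO=K_AO,
            K_BO=K_BO,
            K_IL=K_IL,
            k_on=k_on,
        )

    @property
    def P_AC_nm_s(self) -> float:
        """Apical permeability echoed in nm/s."""
        return self.P_AC / NM_PER_S

    @property
    def P_BC_nm_s(self) -> float:
        """Basolateral permeability echoed in nm/s."""
        return self.P_BC / NM_PER_S

    def with_name(self, name: str) -> "DrugParams":
        return replace(self, name=name)


@dataclass(frozen=True)
class SystemParams:
    """Transwell geometry and system constants.

    Defaults are the fixed values for an MDCKII-MDR1 monolayer in a
    standard transwell insert: apical/basolateral membrane surface
    areas of 2.26e-2 dm^2, chamber volumes of 0.5 mL (apical) and
    1.5 mL (basolateral), a cytoplasm volume of 1 uL, outer-leaflet
    volumes of 5e-10 dm^3 each, a combined inner-leaflet volume of
    1e-9 dm^3 and a residual loss rate constant k_v = 1e-6 /s.
    """

    SA_A: float = 2.26e-2  # dm^2
    SA_B: float = 2.26e-2  # dm^2
    V_A: float = 5e-4      # dm^3
    V_B: float = 1.5e-3    # dm^3
    V_C: float = 1e-6      # dm^3
    V_AO: float = 5e-10    # dm^3
    V_BO: float = 5e-10    # dm^3
    V_IL: float = 1e-9     # dm^3
    k_v: float = 1e-6      # 1/s

    def __post_init__(self) -> None:
        for attr in ("SA_A", "SA_B", "V_A", "V_B", "V_C", "V_AO", "V_BO", "V_IL"):
            _require(getattr(self, attr) > 0, f"{attr} must be > 0")
        _require(self.k_v >= 0, "k_v must be >= 0")


@dataclass(frozen=True)
class Condition:
    """One simulation scenario.

    Parameters
    ----------
    dose
        Initial apical drug concentration (M).
    C_Pgp_tot
        Total P-gp concentration (M); conserved over time.
    t_end
        Simulation horizon (s), default 21600 s (6 h).
    """

    dose: float
    C_Pgp_tot: float
    t_end: float = 21600.0

    def __post_init__(self) -> None:
        _require(self.dose > 0, "dose must be > 0")
        _require(self.C_Pgp_tot >= 0, "C_Pgp_tot must be >= 0")
        _require(self.t_end > 0, "t_end must be > 0")

    @classmethod
    def from_micromolar(
        cls, dose_um: float, pgp_um: float, t_end: float = 21600.0
    ) -> "Condition":
        """Build from dose and P-gp concentration in uM."""
        return cls(dose=dose_um * MICROMOLAR, C_Pgp_tot=pgp_um * MICROMOLAR, t_end=t_end)

    def with_pgp_fraction(self, percent: float) -> "Condition":
        """Condition with total P-gp scaled to ``percent`` % of this one."""
        _require(percent > 0, "expression fraction must be > 0")
        return replace(self, C_Pgp_tot=self.C_Pgp_tot * percent / 100.0)


class EffectiveVolumes(NamedTuple):
    """Drug-accessible compartment volumes (dm^3).

    Instantaneous leaflet partitioning makes each aqueous compartment
    behave as if enlarged by the partition-weighted leaflet volume.
    """

    V_A_tot: float
    V_B_tot: float
    V_C_tot: float


class State(NamedTuple):
    """Model state; see the module docstring for the fields."""

    C_AC: float
    C_CP: float
    C_BC: float
    C_Pgp_free: float
    C_Pgp_bound: float
    A_eff_cum: float
    A_loss_cum: float

    def to_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "State":
        return cls(*np.asarray(y, dtype=float))


def effective_volumes(drug: DrugParams, system: SystemParams) -> EffectiveVolumes:
    """Drug-accessible volumes: V_x_tot = V_x + K * V_leaflet."""
    return EffectiveVolumes(
        V_A_tot=system.V_A + drug.K_AO * system.V_AO,
        V_B_tot=system.V_B + drug.K_BO * system.V_BO,
        V_C_tot=system.V_C + drug.K_IL * system.V_IL,
    )


def initial_state(condition: Condition) -> State:
    """State at t = 0: all drug in the apical chamber, all P-gp free."""
    return State(
        C_AC=condition.dose,
        C_CP=0.0,
        C_BC=0.0,
        C_Pgp_free=condition.C_Pgp_tot,
        C_Pgp_bound=0.0,
        A_eff_cum=0.0,
        A_loss_cum=0.0,
    )


def leaflet_concentrations(
    state: State, drug: DrugParams
) -> tuple[float, float, float]:
    """Lipid-phase drug concentrations (C_AO, C_IL, C_BO) in M.

    Algebraic observables under the instantaneous-equilibration
    assumption: each leaflet concentration is the adjacent aqueous
    concentration times the partition coefficient.
    """
    return (
        drug.K_AO * state.C_AC,
        drug.K_IL * state.C_CP,
        drug.K_BO * state.C_BC,
    )


class _OdeProblem:
    """Precomputed coefficients and vectorised rhs/Jacobian for a scenario.

    Negative state entries are clipped to zero for rate evaluation only
    (the integrator's stored state is untouched); this protects the
    bilinear binding term from sign errors during stiff stepping.
    """

    __slots__ = (
        "a", "b", "q", "k_v", "k_on_KIL", "k_off", "k_e",
        "V_A_tot", "V_B_tot", "V_C_tot",
    )

    def __init__(self, drug: DrugParams, system: SystemParams) -> None:
        vol = effective_volumes(drug, system)
        self.a = drug.P_AC * system.SA_A          # apical diffusion clearance (dm^3/s)
        self.b = drug.P_BC * system.SA_B          # basolateral diffusion clearance
        self.q = 0.5 * system.V_IL                # apical inner-leaflet volume (dm^3)
        self.k_v = system.k_v
        self.k_on_KIL = drug.k_on * drug.K_IL     # binding acts on C_IL = K_IL * C_CP
        self.k_off = drug.k_off
        self.k_e = drug.k_e
        self.V_A_tot = vol.V_A_tot
        self.V_B_tot = vol.V_B_tot
        self.V_C_tot = vol.V_C_tot

    def f(self, t: float, y: np.ndarray) -> np.ndarray:
        if not np.all(np.isfinite(y)):
            raise FloatingPointError(
                f"non-finite state during integration at t={t!r}: {y!r}"
            )
        c_ac, c_cp, c_bc, pf, pb = (max(v, 0.0) for v in y[:5])
        bind = self.k_on_KIL * c_cp * pf
        unbind = self.k_off * pb
        efflux = self.k_e * pb
        d_ac = (
            self.a * (c_cp - c_ac)
            - self.k_v * self.V_A_tot * c_ac
            + self.q * efflux
        ) / self.V_A_tot
        d_cp = (
            self.a * (c_ac - c_cp)
            + self.b * (c_bc - c_cp)
            - self.k_v * self.V_C_tot * c_cp
            - self.q * bind
            + self.q * unbind
        ) / self.V_C_tot
        d_bc = (self.b * (c_cp - c_bc) - self.k_v * self.V_B_tot * c_bc) / self.V_B_tot
        d_pf = -bind + (self.k_off + self.k_e) * pb
        return np.array(
            [
                d_ac,
                d_cp,
                d_bc,
                d_pf,
                -d_pf,
                self.q * efflux,
                self.k_v
                * (
                    self.V_A_tot * c_ac
                    + self.V_C_tot * c_cp
                    + self.V_B_tot * c_bc
                ),
            ]
        )

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        c_cp = max(y[1], 0.0)
        pf = max(y[3], 0.0)
        J = np.zeros((7, 7))
        J[0, 0] = -self.a / self.V_A_tot - self.k_v
        J[0, 1] = self.a / self.V_A_tot
        J[0, 4] = self.q * self.k_e / self.V_A_tot
        J[1, 0] = self.a / self.V_C_tot
        J[1, 1] = (
            -(self.a + self.b) / self.V_C_tot
            - self.k_v
            - self.q * self.k_on_KIL * pf / self.V_C_tot
        )
        J[1, 2] = self.b / self.V_C_tot
        J[1, 3] = -self.q * self.k_on_KIL * c_cp / self.V_C_tot
        J[1, 4] = self.q * self.k_off / self.V_C_tot
        J[2, 1] = self.b / self.V_B_tot
        J[2, 2] = -self.b / self.V_B_tot - self.k_v
        J[3, 1] = -self.k_on_KIL * pf
        J[3, 3] = -self.k_on_KIL * c_cp
        J[3, 4] = self.k_off + self.k_e
        J[4] = -J[3]
        J[5, 4] = self.k_e * self.q
        J[6, 0] = self.k_v * self.V_A_tot
        J[6, 1] = self.k_v * self.V_C_tot
        J[6, 2] = self.k_v * self.V_B_tot
        return J


def rhs(state: State, drug: DrugParams, system: SystemParams) -> State:
    """Time derivative of the model state.

    The chamber balance equations are formulated with the effective
    (drug-accessible) volume multiplying the concentration derivative;
    here the right-hand side is divided through so that a pure
    concentration/amount derivative vector is returned.

    Raises
    ------
    FloatingPointError
        If any state entry is non-finite (signals integration failure).
    """
    problem = _OdeProblem(drug, system)
    return State.from_array(problem.f(0.0, np.asarray(state, dtype=float)))
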