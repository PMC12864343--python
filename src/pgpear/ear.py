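"""The P-gp expression-activity relationship (EAR) statistic.

P-gp activity is measured as the cumulative amount effluxed over the
simulation horizon, ``A_eff_cum(t_end)``.  The relative activity at an
expression level of x% of a reference condition is

    rEAR_x% = 100 * A_eff_cum(x% P-gp) / A_eff_cum(100% P-gp)

A linear expression-activity relationship gives rEAR_x% = x%; values
pinned near 100% at reduced expression indicate a non-linear
relationship where activity barely responds to expression changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drugs import make_virtual_drug
from .model import Condition, DrugParams, SystemParams
from .simulate import SimulationError, cumulative_efflux, simulate

__all__ = [
    "DEFAULT_FRACTIONS",
    "ClassifyThresholds",
    "EarResult",
    "SweepResult",
    "compute_rear",
    "ear_curve",
    "efflux_efficiency",
    "classify_ear",
    "sweep_rear50",
]

#: Expression levels (percent of reference) of the standard EAR curve.
DEFAULT_FRACTIONS: tuple[float, ...] = (2, 7, 15, 30, 50, 100, 200, 300)


@dataclass(frozen=True)
class ClassifyThresholds:
    """Operational cut-offs on rEAR_50% for labelling an EAR curve.

    The underlying behaviour is a continuum; these thresholds are a
    convenience heuristic, not part of the model.
    """

    linear_max: float = 60.0
    nonlinear_min: float = 85.0

    def __post_init__(self) -> None:
        if not 0 < self.linear_max < self.nonlinear_min:
            raise ValueError("need 0 < linear_max < nonlinear_min")


@dataclass(frozen=True)
class EarResult:
    """rEAR values over expression fractions for one drug/condition."""

    drug: str
    reference_condition: Condition
    fractions: tuple[float, ...]
    rear: tuple[float, ...]

    def rear_at(self, x_percent: float) -> float:
        for frac, val in zip(self.fractions, self.rear):
            if frac == x_percent:
                return val
        raise KeyError(f"fraction {x_percent}% not in EAR curve {self.fractions}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug": self.drug,
                "fraction_pct": list(self.fractions),
                "rEAR_pct": list(self.rear),
            }
        )


@dataclass(frozen=True)
class SweepResult:
    """Long-format rEAR_50% grid over (k_off, k_e, dose, reference P-gp).

    ``frame`` holds one record per grid point; points whose simulation
    failed carry NaN and are listed in ``failures`` rather than being
    dropped.
    """

    frame: pd.DataFrame
    failures: tuple[dict, ...] = field(default_factory=tuple)

    @property
    def n_failed(self) -> int:
        return len(self.failures)


def _efflux_for(drug, condition, system, solver) -> float:
    return cumulative_efflux(simulate(drug, condition, system, **solver))


def compute_rear(
    drug: DrugParams,
    condition: Condition,
    x_percent: float,
    system: SystemParams | None = None,
    *,
    reference_efflux: float | None = None,
    **solver,
) -> float:
    """rEAR_x% for one drug under a reference condition.

    Runs the reference simulation (``condition`` as given, the 100%
    expression level) and a second one with total P-gp scaled to
    ``x_percent`` %, and returns the percent ratio of cumulative
    effluxed amounts.  ``reference_efflux`` short-circuits the
    reference simulation when it is already known (curve/sweep reuse).

    Raises
    ------
    ValueError
        If the statistic is undefined (``k_e = 0`` or no P-gp: 0/0).
    """
    if x_percent <= 0:
        raise ValueError("x_percent must be > 0")
    if drug.k_e == 0 or condition.C_Pgp_tot == 0:
        raise ValueError(
            "rEAR undefined: no efflux occurs with k_e = 0 or C_Pgp_tot = 0"
        )
    if reference_efflux is None:
        reference_efflux = _efflux_for(drug, condition, system, solver)
    scaled = _efflux_for(drug, condition.with_pgp_fraction(x_percent), system, solver)
    return 100.0 * scaled / reference_efflux


def ear_curve(
    drug: DrugParams,
    condition: Condition,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    system: SystemParams | None = None,
    **solver,
) -> EarResult:
    """rEAR over a set of expression fractions (one reference simulation).

    The reference (100%) simulation is computed once and reused for
    every fraction; rEAR at x = 100 is therefore exactly 100.
    """
    if not fractions:
        raise ValueError("fractions must be non-empty")
    if any(f <= 0 for f in fractions):
        raise ValueError("all fractions must be > 0")
    if drug.k_e == 0 or condition.C_Pgp_tot == 0:
        raise ValueError(
            "rEAR undefined: no efflux occurs with k_e = 0 or C_Pgp_tot = 0"
        )
    reference = _efflux_for(drug, condition, system, solver)
    rear = tuple(
        100.0
        if f == 100
        else compute_rear(
            drug, condition, f, system, reference_efflux=reference, **solver
        )
        for f in fractions
    )
    return EarResult(
        drug=drug.name,
        reference_condition=condition,
        fractions=tuple(float(f) for f in fractions),
        rear=rear,
    )


def efflux_efficiency(drug: DrugParams) -> float:
    """The ratio k_off/k_e: binding events per successful efflux event.

    Large values mean inefficient efflux (most binding events end in
    dissociation); inefficiently effluxed drugs tend to show linear
    expression-activity relationships.
    """
    if drug.k_e == 0:
        raise ValueError("efflux efficiency undefined for k_e = 0")
    return drug.k_off / drug.k_e


def classify_ear(
    ear: EarResult, thresholds: ClassifyThresholds = ClassifyThresholds()
) -> str:
    """Label an EAR curve by its rEAR_50% value.

    Returns ``"linear"`` (rEAR_50% <= linear_max), ``"non-linear"``
    (>= nonlinear_min) or ``"intermediate"``.
    """
    r50 = ear.rear_at(50)
    if r50 <= thresholds.linear_max:
        return "linear"
    if r50 >= thresholds.nonlinear_min:
        return "non-linear"
    return "intermediate"


def sweep_rear50(
    k_off_grid,
    k_e_grid,
    dose_grid_um,
    pgp_grid_um,
    P_nm_s: float = 300.0,
    K: float = 300.0,
    system: SystemParams | None = None,
    *,
    x_percent: float = 50.0,
    t_end: float = 21600.0,
    **solver,
) -> SweepResult:
    """rEAR at ``x_percent`` over a virtual-drug parameter grid.

    Every combination of dissociation rate constant, efflux rate
    constant, apical dose and reference P-gp expression is simulated
    for a virtual drug with symmetric permeability ``P_nm_s`` and
    uniform partition coefficient ``K``.  A failed grid point is
    recorded (NaN value plus an entry in ``failures``), never silently
    dropped.
    """
    for grid, label in (
        (k_off_grid, "k_off_grid"),
        (k_e_grid, "k_e_grid"),
        (dose_grid_um, "dose_grid_um"),
        (pgp_grid_um, "pgp_grid_um"),
    ):
        if len(list(grid)) == 0:
            raise ValueError(f"{label} must be non-empty")
    records = []
    failures = []
    for k_off in k_off_grid:
        for k_e in k_e_grid:
            drug = make_virtual_drug(k_off, k_e, P_nm_s, K)
            for dose_um in dose_grid_um:
                for pgp_um in pgp_grid_um:
                    condition = Condition.from_micromolar(dose_um, pgp_um, t_end)
                    try:
                        value = compute_rear(
                            drug, condition, x_percent, system, **solver
                        )
                    except SimulationError as err:
                        value = np.nan
                        failures.append(
                            {
                                "k_off_per_s": k_off,
                                "k_e_per_s": k_e,
                                "dose_um": dose_um,
                                "pgp_um": pgp_um,
                                "error": str(err),
                            }
                        )
                    records.append(
                        {
                            "k_off_per_s": float(k_off),
                            "k_e_per_s": float(k_e),
                            "dose_um": float(dose_um),
                            "pgp_um": float(pgp_um),
                            f"rEAR_{x_percent:g}_pct": value,
                        }
                    )
    return SweepResult(frame=pd.DataFrame.from_records(records), failures=tuple(failures))
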