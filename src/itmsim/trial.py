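"""Per-compound ITM trial procedure.

For each virtual compound: (1) find the estimated therapeutic dose —
the minimal IV bolus whose 24-h average receptor occupancy reaches the
target level (default 60%); (2) derive the microdose as the lesser of
1/100th of that dose and the 100 µg regulatory cap; (3) simulate a
single bolus of the microdose into the target extracellular space and
declare ITM success if the 24-h average occupancy again reaches the
target level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .compound import CompoundParams
from .physiology import PhysiologyParams
from .pbpk import (
    DerivedClearances,
    DoseEvent,
    SimResult,
    SimulationFailure,
    average_ro,
    linear_clearances,
    simulate,
)

__all__ = [
    "UNACHIEVABLE",
    "TrialConfig",
    "TrialResult",
    "find_therapeutic_dose",
    "compute_microdose",
    "run_itm",
    "evaluate_compound",
]

#: Sentinel for a therapeutic dose that cannot be reached within the
#: search bounds. +inf keeps dose-threshold filters well-defined.
UNACHIEVABLE = math.inf


@dataclass(frozen=True)
class TrialConfig:
    """Tunable definitions of the ITM trial.

    ``target_avg_ro``: required time-averaged receptor occupancy.
    ``microdose_cap_mass``: regulatory absolute cap in µg (default 100).
    ``microdose_fraction``: regulatory relative cap (default 1/100).
    ``ro_window``: averaging window in hours.
    ``dose_min``/``dose_max``/``n_grid``: log-spaced bracketing grid (µmol).
    ``dose_rel_tol``: relative tolerance of the bisection on dose.
    """

    target_avg_ro: float = 0.60
    microdose_cap_mass: float = 100.0
    microdose_fraction: float = 0.01
    ro_window: tuple[float, float] = (0.0, 24.0)
    dose_min: float = 1e-4
    dose_max: float = 1e5
    n_grid: int = 13
    dose_rel_tol: float = 0.01
    max_bisect: int = 25
    grid_step: float = 0.05
    rtol: float = 1e-8
    atol: float = 1e-12
    receptor_site: str = "intracellular"

    def __post_init__(self):
        if not (0 < self.target_avg_ro < 1):
            raise ValueError("target_avg_ro must lie strictly between 0 and 1")
        if self.microdose_cap_mass < 0 or self.microdose_fraction <= 0:
            raise ValueError("microdose cap and fraction must be positive")
        if not (0 < self.dose_min < self.dose_max):
            raise ValueError("need 0 < dose_min < dose_max")

    def replace(self, **changes) -> "TrialConfig":
        from dataclasses import replace

        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrialResult:
    """Outcome of the three-step ITM procedure for one compound."""

    compound_id: object
    therapeutic_dose: float
    microdose: float
    avg_ro_iv: float
    avg_ro_itm: float
    itm_success: bool
    clearances: DerivedClearances
    solver_failed: bool = False
    n_dose_search_sims: int = 0

    @property
    def evaluated(self) -> bool:
        return not self.solver_failed

    def to_row(self) -> dict:
        return {
            "id": self.compound_id,
            "therapeutic_dose_umol": self.therapeutic_dose,
            "microdose_umol": self.microdose,
            "avg_ro_iv": self.avg_ro_iv,
            "avg_ro_itm": self.avg_ro_itm,
            "itm_success": self.itm_success,
            "CLh": self.clearances.CLh,
            "CLr": self.clearances.CLr,
            "CL_target": self.clearances.CL_target,
            "CL_total": self.clearances.CL_total,
            "solver_failed": self.solver_failed,
        }


def _avg_ro_at_dose(
    compound: CompoundParams,
    physiology: PhysiologyParams,
    dose: float,
    config: TrialConfig,
    route: str = "iv_blood",
    compound_id=None,
) -> float:
    sim = simulate(
        compound,
        physiology,
        [DoseEvent(0.0, dose, route)],
        duration=config.ro_window[1],
        grid=config.grid_step,
        rtol=config.rtol,
        atol=config.atol,
        receptor_site=config.receptor_site,
        compound_id=compound_id,
    )
    return average_ro(sim, config.ro_window)


def find_therapeutic_dose(
    compound: CompoundParams,
    physiology: PhysiologyParams,
    config: TrialConfig | None = None,
    compound_id=None,
) -> tuple[float, float, int]:
    """Minimal IV bolus reaching the required average occupancy.

    Brackets on an ascending log-dose grid, then bisects in log-dose to
    the configured relative tolerance. Returns ``(dose, avg_ro_at_dose,
    n_simulations)``; the dose is ``UNACHIEVABLE`` (with the occupancy
    of the top grid dose) if even ``dose_max`` fails.
    """
    config = config or TrialConfig()
    target = config.target_avg_ro
    grid = np.geomspace(config.dose_min, config.dose_max, config.n_grid)

    n_sims = 0
    lo, hi, ro_hi = None, None, None
    prev = None
    for dose in grid:
        ro = _avg_ro_at_dose(compound, physiology, dose, config, compound_id=compound_id)
        n_sims += 1
        if ro >= target:
            lo, hi, ro_hi = prev, dose, ro
            break
        prev = dose
    if hi is None:
        return UNACHIEVABLE, ro, n_sims

    if lo is None:
        # the lowest dose of the search domain already succeeds
        return hi, ro_hi, n_sims

    for _ in range(config.max_bisect):
        if hi / lo <= 1.0 + config.dose_rel_tol:
            break
        mid = math.sqrt(lo * hi)
        ro = _avg_ro_at_dose(compound, physiology, mid, config, compound_id=compound_id)
        n_sims += 1
        if ro >= target:
            hi, ro_hi = mid, ro
        else:
            lo = mid
    return hi, ro_hi, n_sims


def compute_microdose(
    therapeutic_dose: float,
    molar_mass: float,
    config: TrialConfig | None = None,
) -> float:
    """Microdose (µmol): min(dose/100, cap-mass converted to µmol).

    The 100 µg cap at molar mass 400 g/mol is 0.25 µmol; the sentinel
    for an unachievable therapeutic dose propagates to the capped value.
    """
    config = config or TrialConfig()
    cap_umol = config.microdose_cap_mass / molar_mass
    if therapeutic_dose == UNACHIEVABLE:
        return cap_umol
    if not therapeutic_dose > 0:
        raise ValueError("therapeutic dose must be positive")
    return min(therapeutic_dose * config.microdose_fraction, cap_umol)


def run_itm(
    compound: CompoundParams,
    physiology: PhysiologyParams,
    microdose: float,
    config: TrialConfig | None = None,
    compound_id=None,
) -> tuple[SimResult, bool]:
    """Simulate one microdose bolus into the target extracellular space."""
    config = config or TrialConfig()
    if microdose < 0:
        raise ValueError("microdose must be non-negative")
    sim = simulate(
        compound,
        physiology,
        [DoseEvent(0.0, microdose, "intra_target_extracellular")] if microdose > 0 else [],
        duration=config.ro_window[1],
        grid=config.grid_step,
        rtol=config.rtol,
        atol=config.atol,
        receptor_site=config.receptor_site,
        compound_id=compound_id,
    )
    success = average_ro(sim, config.ro_window) >= config.target_avg_ro
    return sim, success


def evaluate_compound(
    compound: CompoundParams,
    physiology: PhysiologyParams,
    config: TrialConfig | None = None,
    compound_id=None,
) -> TrialResult:
    """Chain dose finding, the microdose rule and the ITM simulation.

    Solver failures never propagate: the result is flagged and the
    surrounding study excludes it from success tallies.
    """
    config = config or TrialConfig()
    clearances = linear_clearances(compound, physiology)
    try:
        dose, ro_iv, n_sims = find_therapeutic_dose(
            compound, physiology, config, compound_id=compound_id
        )
        if dose == UNACHIEVABLE:
            return TrialResult(
                compound_id=compound_id,
                therapeutic_dose=UNACHIEVABLE,
                microdose=compute_microdose(UNACHIEVABLE, compound.molar_mass, config),
                avg_ro_iv=ro_iv,
                avg_ro_itm=float("nan"),
                itm_success=False,
                clearances=clearances,
                n_dose_search_sims=n_sims,
            )
        microdose = compute_microdose(dose, compound.molar_mass, config)
        sim, success = run_itm(
            compound, physiology, microdose, config, compound_id=compound_id
        )
        return TrialResult(
            compound_id=compound_id,
            therapeutic_dose=dose,
            microdose=microdose,
            avg_ro_iv=ro_iv,
            avg_ro_itm=average_ro(sim, config.ro_window),
            itm_success=success,
            clearances=clearances,
            n_dose_search_sims=n_sims,
        )
    except SimulationFailure:
        return TrialResult(
            compound_id=compound_id,
            therapeutic_dose=float("nan"),
            microdose=float("nan"),
            avg_ro_iv=float("nan"),
            avg_ro_itm=float("nan"),
            itm_success=False,
            clearances=clearances,
            solver_failed=True,
        )
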