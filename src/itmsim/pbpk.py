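"""PBPK model with explicit drug-receptor binding.

Nine-state whole-body model in amount units (µmol):

* one well-mixed blood compartment receiving all venous returns,
* flow-limited adipose, muscle and skin with tissue:blood partition
  coefficients Kp,
* a permeability-limited liver split into an extracellular space that
  the hepatic blood flow traverses and a hepatocellular space reached by
  saturable active uptake plus bidirectional passive diffusion, with
  saturable metabolism inside the cell (extended clearance concept),
* a permeability-limited target tissue mirroring the liver structure,
  holding the receptor pool; binding follows mass action,
  dRC/dt = kon*C_free*(Rtot - RC) - koff*RC with kon = koff/Kd.

Unbound fraction fub applies to blood and every extracellular space;
the intracellular unbound fraction is 1. Renal elimination acts on the
total blood concentration. The stiff system is integrated with LSODA
using an analytic Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import odeint
from scipy.integrate._odepack_py import ODEintWarning

from .compound import CompoundParams
from .physiology import PhysiologyParams

__all__ = [
    "COMPARTMENTS",
    "DoseEvent",
    "SimResult",
    "DerivedClearances",
    "SimulationFailure",
    "pbpk_derivatives",
    "simulate",
    "average_ro",
    "linear_clearances",
]

COMPARTMENTS = (
    "blood",
    "adipose",
    "muscle",
    "skin",
    "liver_ec",
    "liver_ic",
    "target_ec",
    "target_ic_free",
    "receptor_complex",
)

N_STATES = len(COMPARTMENTS)

Route = Literal["iv_blood", "intra_target_extracellular"]
_ROUTE_COMPARTMENT = {"iv_blood": 0, "intra_target_extracellular": 6}

ReceptorSite = Literal["intracellular", "extracellular"]

# Parameter-vector layout shared by the jitted RHS/Jacobian.
(_VB, _QA, _QH, _QM, _QS, _QT, _VA, _VM, _VS, _VHE, _VHIC, _VT, _VTIC,
 _KPA, _KPM, _KPS, _FUB, _CLR,
 _VMU, _KMU, _VMM, _KMM, _PS,
 _VMTU, _KMTU, _PST, _VMTM, _KMTM,
 _KON, _KOFF, _XR, _INF, _SITE) = range(33)


class SimulationFailure(RuntimeError):
    """LSODA failed to integrate a compound; carries the compound identity."""

    def __init__(self, message: str, compound_id=None):
        super().__init__(message)
        self.compound_id = compound_id


def _pack_params(
    compound: CompoundParams,
    physiology: PhysiologyParams,
    infusion_rate: float = 0.0,
    receptor_site: ReceptorSite = "intracellular",
) -> np.ndarray:
    c, ph = compound, physiology
    return np.array(
        [
            ph.Vb, ph.Qa, ph.Qh, ph.Qm, ph.Qs, ph.Qt,
            ph.Va, ph.Vm, ph.Vs, ph.Vhe, ph.Vh_ic, ph.Vt, ph.Vt_ic,
            c.Kpa, c.Kpm, c.Kps, c.fub, c.CLr,
            c.Vmax_uptake, c.Km_uptake, c.Vmax_met, c.Km_met, c.PSdif_inf,
            c.Vmax_targetUptake, c.Km_targetUptake, c.PSdiff_target,
            c.Vmax_targetMet, c.Km_targetMet,
            c.kon, c.koff, c.X_TotalR,
            infusion_rate,
            0.0 if receptor_site == "intracellular" else 1.0,
        ],
        dtype=np.float64,
    )


@njit(cache=True)
def _rhs(y, t, p):
    out = np.empty(9)
    Cb = y[0] / p[_VB]

    # flow-limited tissues: dA/dt = Q*(Cb - C/Kp)
    ret_a = p[_QA] * y[1] / (p[_VA] * p[_KPA])
    ret_m = p[_QM] * y[2] / (p[_VM] * p[_KPM])
    ret_s = p[_QS] * y[3] / (p[_VS] * p[_KPS])
    out[1] = p[_QA] * Cb - ret_a
    out[2] = p[_QM] * Cb - ret_m
    out[3] = p[_QS] * Cb - ret_s

    # liver: blood traverses the extracellular space
    Cec = y[4] / p[_VHE]
    Cu = p[_FUB] * Cec
    upt = p[_VMU] * Cu / (p[_KMU] + Cu) + p[_PS] * Cu
    Cic = y[5] / p[_VHIC]
    eff = p[_PS] * Cic
    met = p[_VMM] * Cic / (p[_KMM] + Cic)
    out[4] = p[_QH] * (Cb - Cec) - upt + eff
    out[5] = upt - eff - met

    # target tissue, same structure
    Ctec = y[6] / p[_VT]
    Cut = p[_FUB] * Ctec
    uptT = p[_VMTU] * Cut / (p[_KMTU] + Cut) + p[_PST] * Cut
    Ctic = y[7] / p[_VTIC]
    effT = p[_PST] * Ctic
    metT = p[_VMTM] * Ctic / (p[_KMTM] + Ctic)

    # receptor binding on the free local concentration
    if p[_SITE] == 0.0:
        cbind = Ctic
    else:
        cbind = Cut
    bind = p[_KON] * cbind * (p[_XR] - y[8]) - p[_KOFF] * y[8]

    out[6] = p[_QT] * (Cb - Ctec) - uptT + effT
    out[7] = uptT - effT - metT
    if p[_SITE] == 0.0:
        out[7] -= bind
    else:
        out[6] -= bind
    out[8] = bind

    out[0] = (
        ret_a + ret_m + ret_s
        + p[_QH] * Cec + p[_QT] * Ctec
        - (p[_QA] + p[_QH] + p[_QM] + p[_QS] + p[_QT]) * Cb
        - p[_CLR] * Cb
        + p[_INF]
    )
    return out


@njit(cache=True)
def _jac(y, t, p):
    J = np.zeros((9, 9))
    ka = p[_QA] / (p[_VA] * p[_KPA])
    km = p[_QM] / (p[_VM] * p[_KPM])
    ks = p[_QS] / (p[_VS] * p[_KPS])
    Qsum = p[_QA] + p[_QH] + p[_QM] + p[_QS] + p[_QT]

    J[0, 0] = -(Qsum + p[_CLR]) / p[_VB]
    J[0, 1] = ka
    J[0, 2] = km
    J[0, 3] = ks
    J[0, 4] = p[_QH] / p[_VHE]
    J[0, 6] = p[_QT] / p[_VT]

    J[1, 0] = p[_QA] / p[_VB]
    J[1, 1] = -ka
    J[2, 0] = p[_QM] / p[_VB]
    J[2, 2] = -km
    J[3, 0] = p[_QS] / p[_VB]
    J[3, 3] = -ks

    Cu = p[_FUB] * y[4] / p[_VHE]
    dupt = (p[_VMU] * p[_KMU] / (p[_KMU] + Cu) ** 2 + p[_PS]) * p[_FUB] / p[_VHE]
    Cic = y[5] / p[_VHIC]
    dmet = p[_VMM] * p[_KMM] / (p[_KMM] + Cic) ** 2 / p[_VHIC]
    J[4, 0] = p[_QH] / p[_VB]
    J[4, 4] = -p[_QH] / p[_VHE] - dupt
    J[4, 5] = p[_PS] / p[_VHIC]
    J[5, 4] = dupt
    J[5, 5] = -p[_PS] / p[_VHIC] - dmet

    Cut = p[_FUB] * y[6] / p[_VT]
    duptT = (p[_VMTU] * p[_KMTU] / (p[_KMTU] + Cut) ** 2 + p[_PST]) * p[_FUB] / p[_VT]
    Ctic = y[7] / p[_VTIC]
    dmetT = p[_VMTM] * p[_KMTM] / (p[_KMTM] + Ctic) ** 2 / p[_VTIC]

    J[6, 0] = p[_QT] / p[_VB]
    J[6, 6] = -p[_QT] / p[_VT] - duptT
    J[6, 7] = p[_PST] / p[_VTIC]
    J[7, 6] = duptT
    J[7, 7] = -p[_PST] / p[_VTIC] - dmetT

    Rfree = p[_XR] - y[8]
    if p[_SITE] == 0.0:
        cbind = Ctic
        dbind_dc = p[_KON] * Rfree / p[_VTIC]
        J[7, 7] -= dbind_dc
        J[7, 8] = p[_KON] * cbind + p[_KOFF]
        J[8, 7] = dbind_dc
    else:
        cbind = Cut
        dbind_dc = p[_KON] * Rfree * p[_FUB] / p[_VT]
        J[6, 6] -= dbind_dc
        J[6, 8] = p[_KON] * cbind + p[_KOFF]
        J[8, 6] = dbind_dc
    J[8, 8] = -(p[_KON] * cbind + p[_KOFF])
    return J


@dataclass(frozen=True)
class DoseEvent:
    """A bolus of ``amount`` µmol given at ``time`` h via ``route``."""

    time: float
    amount: float
    route: Route = "iv_blood"

    def __post_init__(self):
        if self.amount < 0:
            raise ValueError("dose amount must be non-negative")
        if self.time < 0:
            raise ValueError("dose time must be non-negative")
        if self.route not in _ROUTE_COMPARTMENT:
            raise ValueError(f"unknown route {self.route!r}")


@dataclass(frozen=True)
class DerivedClearances:
    """Linear-limit organ clearances (L/h)."""

    CLh: float
    CL_target: float
    CLr: float

    @property
    def CL_total(self) -> float:
        return self.CLh + self.CLr + self.CL_target


@dataclass
class SimResult:
    """Trajectories of all compartment amounts plus receptor occupancy."""

    times: np.ndarray
    amounts: np.ndarray  # shape (n_times, 9), columns per COMPARTMENTS
    ro: np.ndarray
    avg_ro: float
    compound_id: object = None
    compartments: tuple = field(default=COMPARTMENTS, repr=False)

    def amount(self, compartment: str) -> np.ndarray:
        return self.amounts[:, COMPARTMENTS.index(compartment)]

    @property
    def total_amount(self) -> np.ndarray:
        return self.amounts.sum(axis=1)

    def to_tidy_frame(self) -> pd.DataFrame:
        frames = []
        for i, name in enumerate(COMPARTMENTS):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "compartment": name,
                        "amount": self.amounts[:, i],
                        "ro": self.ro,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_tidy_frame().to_csv(path, index=False)


def pbpk_derivatives(
    state: np.ndarray,
    compound: CompoundParams,
    physiology: PhysiologyParams,
    infusion_rate: float = 0.0,
    receptor_site: ReceptorSite = "intracellular",
) -> np.ndarray:
    """Time derivatives (µmol/h) of the nine compartment amounts."""
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ValueError(f"state must have shape ({N_STATES},)")
    if not np.all(np.isfinite(state)) or np.any(state < 0):
        raise SimulationFailure("state contains NaN/negative amounts")
    p = _pack_params(compound, physiology, infusion_rate, receptor_site)
    return _rhs(state, 0.0, p)


def _integrate_segment(y0, ts, p, rtol, atol):
    if len(ts) == 1:
        return y0[None, :]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ODEintWarning)
        sol, info = odeint(
        _rhs,
        y0,
        ts,
        args=(p,),
        Dfun=_jac,
        rtol=rtol,
        atol=atol,
        mxstep=500000,
        full_output=True,
        printmessg=False,
    )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(sol)):
        raise SimulationFailure(f"LSODA failed: {info['message']}")
    return sol


def simulate(
    compound: CompoundParams,
    physiology: PhysiologyParams,
    doses: Sequence[DoseEvent],
    duration: float = 24.0,
    grid: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    infusion_rate: float = 0.0,
    receptor_site: ReceptorSite = "intracellular",
    compound_id=None,
) -> SimResult:
    """Integrate the model for a dosing schedule and return trajectories.

    Bolus events are applied as instantaneous amount jumps in the
    route's compartment; the solver is restarted at every event time.
    ``avg_ro`` is the trapezoidal mean of the occupancy curve over the
    first 24 h (or the full span if shorter).
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    doses = sorted(doses, key=lambda d: d.time)
    if any(d.time > duration for d in doses):
        raise ValueError("dose event beyond the simulated duration")

    n_steps = int(round(duration / grid))
    times = np.linspace(0.0, n_steps * grid, n_steps + 1)
    p = _pack_params(compound, physiology, infusion_rate, receptor_site)

    y = np.zeros(N_STATES)
    out = np.zeros((len(times), N_STATES))

    # segment boundaries at the dose event times
    event_times = sorted({d.time for d in doses})
    boundaries = [0.0] + [t for t in event_times if t > 0] + [times[-1]]
    boundaries = sorted(set(boundaries))

    for d in doses:
        if d.time == 0.0:
            y[_ROUTE_COMPARTMENT[d.route]] += d.amount
    out[0] = y

    try:
        for lo, hi in zip(boundaries[:-1], boundaries[1:]):
            mask = (times > lo + 1e-12) & (times <= hi + 1e-12)
            seg_ts = np.concatenate(([lo], times[mask]))
            if seg_ts[-1] < hi - 1e-12:
                seg_ts = np.concatenate((seg_ts, [hi]))
            sol = _integrate_segment(y, seg_ts, p, rtol, atol)
            n_grid_pts = int(mask.sum())
            if n_grid_pts:
                out[np.where(mask)[0]] = sol[1 : 1 + n_grid_pts]
            y = sol[-1].copy()
            for d in doses:
                if abs(d.time - hi) < 1e-12 and d.time > 0:
                    y[_ROUTE_COMPARTMENT[d.route]] += d.amount
    except SimulationFailure as exc:
        raise SimulationFailure(str(exc), compound_id=compound_id) from None

    # clip solver-tolerance-level negative excursions
    np.clip(out, 0.0, None, out=out)
    ro = out[:, 8] / compound.X_TotalR
    np.clip(ro, 0.0, 1.0, out=ro)

    result = SimResult(times=times, amounts=out, ro=ro, avg_ro=0.0, compound_id=compound_id)
    window_end = min(24.0, times[-1])
    result.avg_ro = average_ro(result, (0.0, window_end))
    return result


def average_ro(sim: SimResult, window: tuple[float, float]) -> float:
    """Time-averaged receptor occupancy over ``window`` (trapezoidal AUC / width)."""
    t0, t1 = window
    if not (t1 > t0):
        raise ValueError("RO averaging window must have positive width")
    if t0 < sim.times[0] - 1e-9 or t1 > sim.times[-1] + 1e-9:
        raise ValueError("RO averaging window outside the simulated span")
    grid = np.unique(np.clip(np.concatenate(([t0], sim.times, [t1])), t0, t1))
    ro = np.interp(grid, sim.times, sim.ro)
    return float(np.trapezoid(ro, grid) / (t1 - t0))


def linear_clearances(
    compound: CompoundParams, physiology: PhysiologyParams
) -> DerivedClearances:
    """Organ blood clearances in the linear (trace-concentration) limit.

    Hepatic: well-stirred form CLh = Qh*fub*CLint/(Qh + fub*CLint) with
    the extended-clearance intrinsic term
    CLint = (Vmax_up/Km_up + PSdif) * CLmet / (PSdif + CLmet),
    CLmet = Vmax_met/Km_met. The target organ uses the same form with
    its own uptake, diffusion and metabolism parameters and blood flow.
    """
    c = compound

    def organ(Q, vmax_up, km_up, ps, vmax_met, km_met):
        clmet = vmax_met / km_met
        if clmet == 0.0:
            return 0.0
        clint = (vmax_up / km_up + ps) * clmet / (ps + clmet)
        return Q * c.fub * clint / (Q + c.fub * clint)

    CLh = organ(physiology.Qh, c.Vmax_uptake, c.Km_uptake, c.PSdif_inf,
                c.Vmax_met, c.Km_met)
    CLt = organ(physiology.Qt, c.Vmax_targetUptake, c.Km_targetUptake,
                c.PSdiff_target, c.Vmax_targetMet, c.Km_targetMet)
    return DerivedClearances(CLh=CLh, CL_target=CLt, CLr=c.CLr)
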