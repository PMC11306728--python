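"""Model-level oracles: mass balance, analytic limits, binding equilibrium."""

import numpy as np
import pytest

from itmsim import (
    COMPARTMENTS,
    DoseEvent,
    average_ro,
    linear_clearances,
    pbpk_derivatives,
    sample_compounds,
    simulate,
)
from itmsim.pbpk import SimulationFailure

from conftest import zero_elimination


# ---------------------------------------------------------------- derivatives

def test_zero_state_zero_rates(median_compound, phys):
    rates = pbpk_derivatives(np.zeros(9), median_compound, phys)
    assert np.all(rates == 0.0)


def test_rate_sum_is_zero_without_elimination(median_compound, phys):
    """Total drug amount is conserved when no pathway eliminates drug."""
    compound = zero_elimination(median_compound)
    rng = np.random.default_rng(7)
    for _ in range(20):
        state = rng.exponential(1.0, size=9)
        state[8] = min(state[8], compound.X_TotalR)  # RC cannot exceed the pool
        rates = pbpk_derivatives(state, compound, phys)
        assert abs(rates.sum()) < 1e-9 * max(np.abs(rates).max(), 1.0)


def test_pure_dissociation(median_compound, phys):
    """Full receptor pool with no free drug decays at -koff*Rtot."""
    state = np.zeros(9)
    state[8] = median_compound.X_TotalR
    rates = pbpk_derivatives(state, median_compound, phys)
    assert rates[8] == pytest.approx(-median_compound.koff * median_compound.X_TotalR)
    # the dissociated drug reappears as free intracellular target drug
    assert rates[7] == pytest.approx(median_compound.koff * median_compound.X_TotalR)


def test_invalid_state_rejected(median_compound, phys):
    with pytest.raises(SimulationFailure):
        pbpk_derivatives(np.full(9, np.nan), median_compound, phys)
    with pytest.raises(SimulationFailure):
        pbpk_derivatives(-np.ones(9), median_compound, phys)


# ------------------------------------------------------------------- simulate

def test_no_dose_stays_zero(median_compound, phys):
    sim = simulate(median_compound, phys, [], duration=12.0)
    assert np.all(sim.amounts == 0.0)
    assert sim.avg_ro == 0.0


def test_mass_conservation_without_elimination(median_compound, phys):
    """With elimination off, a 1 µmol bolus is conserved over 240 h."""
    rtol = 1e-8
    compound = zero_elimination(median_compound)
    sim = simulate(compound, phys, [DoseEvent(0.0, 1.0)], duration=240.0, grid=0.5, rtol=rtol)
    assert np.abs(sim.total_amount - 1.0).max() < 10 * rtol


def test_one_compartment_collapse(median_compound, phys):
    """All tissue exchange off: blood follows Dose*exp(-CLr*t/Vb) to 0.1%."""
    phys0 = phys.replace(Qa=1e-300, Qh=1e-300, Qm=1e-300, Qs=1e-300, Qt=1e-300)
    compound = median_compound.replace(
        Vmax_uptake=1e-300, Vmax_met=1e-300, PSdif_inf=1e-300,
        Vmax_targetUptake=1e-300, PSdiff_target=1e-300, Vmax_targetMet=1e-300,
        CLr=5.0,
    )
    sim = simulate(compound, phys0, [DoseEvent(0.0, 1.0)], duration=24.0, grid=0.1)
    expected = np.exp(-5.0 * sim.times / phys.Vb)
    assert np.abs(sim.amount("blood") - expected).max() < 1e-3 * expected.max()


def test_linear_steady_state_infusion(median_compound, phys):
    """Css = rate/CL_total in the linear regime, within 2%."""
    cl_total = linear_clearances(median_compound, phys).CL_total
    rate = 1e-6  # µmol/h, far below every Km*V
    sim = simulate(median_compound, phys, [], duration=3000.0, grid=5.0, infusion_rate=rate)
    css = sim.amount("blood")[-1] / phys.Vb
    assert css == pytest.approx(rate / cl_total, rel=0.02)


def test_bolus_event_mid_run(median_compound, phys):
    """A bolus at t=6 h jumps the total amount by exactly its size."""
    compound = zero_elimination(median_compound)
    sim = simulate(
        compound, phys,
        [DoseEvent(0.0, 1.0), DoseEvent(6.0, 2.0)],
        duration=24.0, grid=0.25,
    )
    before = sim.total_amount[sim.times <= 6.0 - 0.25]
    after = sim.total_amount[sim.times > 6.0]
    assert np.allclose(before, 1.0, atol=1e-6)
    assert np.allclose(after, 3.0, atol=1e-6)


def test_nonnegative_states_random_compounds(phys):
    """No compartment goes negative across a random compound population."""
    compounds = sample_compounds(1000, seed=99)
    rng = np.random.default_rng(5)
    for i, compound in enumerate(compounds):
        dose = float(rng.choice([0.01, 1.0, 100.0]))
        route = "iv_blood" if i % 2 == 0 else "intra_target_extracellular"
        sim = simulate(compound, phys, [DoseEvent(0.0, dose, route)], duration=24.0, grid=0.5)
        assert sim.amounts.min() >= 0.0  # clipped from >= -atol excursions
        assert np.all(sim.amount("receptor_complex") <= compound.X_TotalR * (1 + 1e-9))
        assert np.all((0.0 <= sim.ro) & (sim.ro <= 1.0))


def test_ro_is_complex_over_total(median_compound, phys):
    sim = simulate(median_compound, phys, [DoseEvent(0.0, 1.0)])
    expected = sim.amount("receptor_complex") / median_compound.X_TotalR
    assert np.allclose(sim.ro, expected)


def test_dose_monotonicity_of_average_ro(phys, small_population):
    """Doubling the IV dose never lowers the average occupancy."""
    for compound in small_population[:6]:
        ro = [
            simulate(compound, phys, [DoseEvent(0.0, d)], duration=24.0).avg_ro
            for d in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(ro, ro[1:]))


def test_tidy_export_roundtrip(tmp_path, median_compound, phys):
    sim = simulate(median_compound, phys, [DoseEvent(0.0, 1.0)], duration=2.0, grid=0.5)
    path = tmp_path / "sim.csv"
    sim.to_csv(path)
    import pandas as pd

    frame = pd.read_csv(path)
    assert set(frame["compartment"]) == set(COMPARTMENTS)
    assert len(frame) == len(sim.times) * len(COMPARTMENTS)


# ----------------------------------------------------------------- average RO

def test_average_ro_constant_curves(median_compound, phys):
    sim = simulate(median_compound, phys, [], duration=24.0)
    assert average_ro(sim, (0.0, 24.0)) == 0.0
    sim.ro = np.full_like(sim.ro, 0.6)
    assert average_ro(sim, (0.0, 24.0)) == pytest.approx(0.6)
    assert average_ro(sim, (3.0, 7.5)) == pytest.approx(0.6)


def test_average_ro_window_validation(median_compound, phys):
    sim = simulate(median_compound, phys, [], duration=10.0)
    with pytest.raises(ValueError):
        average_ro(sim, (5.0, 5.0))
    with pytest.raises(ValueError):
        average_ro(sim, (0.0, 11.0))


def test_equilibrium_occupancy_at_kd(median_compound, phys):
    """Free target concentration held at Kd gives 50% occupancy.

    Harness: bolus into the target with fast symmetric diffusion, no
    elimination, no washout (Qt ~ 0) and a vanishing receptor pool, so
    the free intracellular concentration settles at dose/(Vt+Vt_ic);
    the dose is chosen to make that equal Kd.
    """
    compound = median_compound.replace(
        Vmax_met=1e-300, Vmax_targetMet=1e-300, CLr=1e-300,
        Vmax_uptake=1e-300, Vmax_targetUptake=1e-300, PSdif_inf=1e-300,
        PSdiff_target=50.0, fub=1.0, koff=2.0, X_TotalR=1e-10,
    )
    phys0 = phys.replace(Qt=1e-300)
    dose = compound.Kd * (phys.Vt + phys.Vt_ic)
    sim = simulate(
        compound, phys0,
        [DoseEvent(0.0, dose, "intra_target_extracellular")],
        duration=24.0,
    )
    # equilibrium reached well after 1/koff = 0.5 h
    assert sim.ro[-1] == pytest.approx(0.5, rel=0.01)
    assert average_ro(sim, (10.0, 24.0)) == pytest.approx(0.5, rel=0.01)


def test_equilibrium_occupancy_curve(median_compound, phys):
    """Occupancy follows C/(C+Kd) across concentrations (monotone in C)."""
    compound = median_compound.replace(
        Vmax_met=1e-300, Vmax_targetMet=1e-300, CLr=1e-300,
        Vmax_uptake=1e-300, Vmax_targetUptake=1e-300, PSdif_inf=1e-300,
        PSdiff_target=50.0, fub=1.0, koff=2.0, X_TotalR=1e-10,
    )
    phys0 = phys.replace(Qt=1e-300)
    ros = []
    for mult in (0.25, 1.0, 4.0):
        conc = mult * compound.Kd
        dose = conc * (phys.Vt + phys.Vt_ic)
        sim = simulate(
            compound, phys0,
            [DoseEvent(0.0, dose, "intra_target_extracellular")],
            duration=24.0,
        )
        assert sim.ro[-1] == pytest.approx(conc / (conc + compound.Kd), rel=0.01)
        ros.append(sim.ro[-1])
    assert ros == sorted(ros)


# ----------------------------------------------------------------- clearances

def test_flow_limited_hepatic_clearance(median_compound, phys):
    """Infinite intrinsic clearance drives CLh to the hepatic blood flow."""
    compound = median_compound.replace(Vmax_met=1e12, Vmax_uptake=1e12, fub=1.0)
    cl = linear_clearances(compound, phys)
    assert cl.CLh == pytest.approx(phys.Qh, rel=1e-4)


def test_no_metabolism_no_hepatic_clearance(median_compound, phys):
    compound = median_compound.replace(Vmax_met=0.0)
    assert linear_clearances(compound, phys).CLh == 0.0


def test_restrictive_clearance_limit(median_compound, phys):
    """fub*CLint << Qh: CLh approaches fub*CLint within 1%."""
    c = median_compound.replace(Vmax_uptake=0.1, PSdif_inf=0.05, Vmax_met=0.25, fub=0.1)
    clmet = c.Vmax_met / c.Km_met
    clint = (c.Vmax_uptake / c.Km_uptake + c.PSdif_inf) * clmet / (c.PSdif_inf + clmet)
    cl = linear_clearances(c, phys)
    assert cl.CLh == pytest.approx(c.fub * clint, rel=0.01)


def test_clearance_bounds_on_population(phys, small_population):
    for compound in small_population:
        cl = linear_clearances(compound, phys)
        assert 0.0 <= cl.CLh < phys.Qh
        assert 0.0 <= cl.CL_target < phys.Qt
        assert cl.CL_total >= cl.CLr


def test_receptor_site_switch(median_compound, phys):
    """The extracellular-receptor variant also conserves mass and binds."""
    compound = zero_elimination(median_compound)
    sim = simulate(
        compound, phys,
        [DoseEvent(0.0, 0.1, "intra_target_extracellular")],
        duration=24.0, receptor_site="extracellular",
    )
    assert np.abs(sim.total_amount - 0.1).max() < 1e-6
    assert sim.avg_ro > 0.0
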