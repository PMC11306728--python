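import numpy as np
import pytest

from itmsim import build_physiology, make_compound, sample_compounds


@pytest.fixture(scope="session")
def phys():
    return build_physiology(75.0)


@pytest.fixture(scope="session")
def median_compound():
    """A compound at (roughly) the median of every sampled parameter."""
    return make_compound(
        Vmax_uptake=100.0, Km_uptake=1.0, Vmax_met=250.0, Km_met=10.0,
        PSdif_inf=30.0,
        Vmax_targetUptake=0.192, Km_targetUptake=1.0, PSdiff_target=0.115,
        Vmax_targetMet=0.192, Km_targetMet=10.0,
        Kd=0.00134, koff=1.0, X_TotalR=0.01,
        fub=0.5, CLr=3.0, Kp_scaling=3.3,
    )


@pytest.fixture(scope="session")
def small_population():
    """A reproducible handful of random virtual compounds."""
    return list(sample_compounds(12, seed=424242))


def zero_elimination(compound):
    """Switch off every elimination pathway (metabolism and renal)."""
    return compound.replace(Vmax_met=1e-300, Vmax_targetMet=1e-300, CLr=1e-300)
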