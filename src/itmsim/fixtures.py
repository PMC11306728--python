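"""Small on-disk fixture sets for demos and round-trip checks."""

from __future__ import annotations

from pathlib import Path

from .compound import make_compound, write_compound_yaml
from .physiology import build_physiology
from .sampling import GenerationConfig, sample_compounds
from .trial import TrialConfig, evaluate_compound

__all__ = ["generate_fixtures", "expected_success_compound", "expected_failure_compound"]


def expected_success_compound():
    """Hand-tuned compound expected to achieve ITM success.

    Sub-nanomolar affinity, slow dissociation, moderate receptor pool
    and high hepatic clearance: the therapeutic dose stays under 10 mg
    so the full 1/100 microdose applies, and the occupancy is retained
    locally after intra-target administration.
    """
    return make_compound(
        Vmax_uptake=300.0, Km_uptake=1.0, Vmax_met=800.0, Km_met=10.0,
        PSdif_inf=100.0,
        Vmax_targetUptake=0.5, Km_targetUptake=1.0, PSdiff_target=0.3,
        Vmax_targetMet=0.5, Km_targetMet=10.0,
        Kd=3e-4, koff=0.25, X_TotalR=0.01,
        fub=0.5, CLr=5.0, Kp_scaling=3.0,
    )


def expected_failure_compound():
    """Compound that cannot succeed: receptor pool above the microdose cap.

    With 0.5 µmol of receptor and the microdose capped at 0.25 µmol
    (100 µg at molar mass 400), occupancy can never exceed 50%.
    """
    return make_compound(
        Vmax_uptake=100.0, Km_uptake=1.0, Vmax_met=250.0, Km_met=10.0,
        PSdif_inf=30.0,
        Vmax_targetUptake=0.2, Km_targetUptake=1.0, PSdiff_target=0.1,
        Vmax_targetMet=0.2, Km_targetMet=10.0,
        Kd=2e-3, koff=1.0, X_TotalR=0.5,
        fub=0.2, CLr=3.0, Kp_scaling=3.0,
    )


REFERENCE_TEMPLATE = """\
compound,value,parameter
example_drug_1,0.001,Kd_uM
example_drug_2,0.004,Kd_uM
example_drug_1,0.5,koff_per_h
example_drug_1,0.35,fu
example_drug_1,25.0,CL_L_per_h
example_drug_1,12.0,bioavailable_dose_mg
"""


def generate_fixtures(seed: int, out_dir: str | Path, verify: bool = True) -> dict:
    """Write a 20-compound population, the two hand-tuned compounds and
    a reference-CSV template; optionally verify the expected outcomes by
    simulation. Regeneration with the same seed is byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    population = sample_compounds(20, seed, GenerationConfig())
    population.to_csv(out / "population.csv")

    success = expected_success_compound()
    failure = expected_failure_compound()
    write_compound_yaml(success, out / "expected-success.yaml")
    write_compound_yaml(failure, out / "expected-failure.yaml")
    (out / "reference_template.csv").write_text(REFERENCE_TEMPLATE)

    outcomes = {}
    if verify:
        phys = build_physiology()
        config = TrialConfig()
        for name, compound in (("expected-success", success), ("expected-failure", failure)):
            result = evaluate_compound(compound, phys, config, compound_id=name)
            outcomes[name] = result.itm_success
        if not outcomes["expected-success"] or outcomes["expected-failure"]:
            raise RuntimeError(f"fixture outcomes differ from construction: {outcomes}")
    return outcomes
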