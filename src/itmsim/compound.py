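"""Virtual compound parameterisation and serialisation.

A compound is described by the hepatic disposition parameters of the
extended clearance concept (saturable sinusoidal uptake, bidirectional
passive diffusion, saturable metabolism), their target-tissue analogues,
receptor binding kinetics (Kd, koff, total receptor abundance), plasma
protein binding, renal clearance and flow-limited tissue partition
coefficients. Amount units are µmol, concentrations µM, times hours.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace, fields
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

#: Fixed molar mass assumed for every virtual small molecule (g/mol).
DEFAULT_MOLAR_MASS = 400.0

#: Tissue:blood partition coefficients relative to the common scaling factor.
KP_TISSUE_FACTORS = {"Kpa": 0.1, "Kpm": 0.2, "Kps": 0.5}


@dataclass(frozen=True)
class CompoundParams:
    """One virtual compound.

    Saturable rates are whole-body Vmax values in µmol/h with
    Michaelis constants in µM; diffusional clearances in L/h.
    ``fub`` is the unbound fraction, taken equal in plasma and blood
    and applied to blood and all extracellular spaces; the
    intracellular unbound fraction is 1.
    """

    Vmax_uptake: float
    Km_uptake: float
    Vmax_met: float
    Km_met: float
    PSdif_inf: float
    Vmax_targetUptake: float
    Km_targetUptake: float
    PSdiff_target: float
    Vmax_targetMet: float
    Km_targetMet: float
    Kd: float
    koff: float
    X_TotalR: float
    fub: float
    CLr: float
    Kp_scaling: float
    Kpa: float
    Kpm: float
    Kps: float
    molar_mass: float = DEFAULT_MOLAR_MASS

    @property
    def kon(self) -> float:
        """Association rate constant (1/µM/h), kon = koff / Kd."""
        return self.koff / self.Kd

    def validate(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"compound field {f.name!r} must be > 0, got {value}")
        if self.fub > 1:
            raise ValueError(f"unbound fraction fub must be <= 1, got {self.fub}")
        for name, factor in KP_TISSUE_FACTORS.items():
            expected = factor * self.Kp_scaling
            if abs(getattr(self, name) - expected) > 1e-9 * max(expected, 1e-300):
                raise ValueError(
                    f"{name} must equal {factor}*Kp_scaling = {expected}"
                )

    def replace(self, **changes) -> "CompoundParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


COMPOUND_COLUMNS = [f.name for f in fields(CompoundParams)]


def make_compound(Kp_scaling: float = 1.0, **kwargs) -> CompoundParams:
    """Construct a compound, filling Kpa/Kpm/Kps from ``Kp_scaling``."""
    for name, factor in KP_TISSUE_FACTORS.items():
        kwargs.setdefault(name, factor * Kp_scaling)
    return CompoundParams(Kp_scaling=Kp_scaling, **kwargs)


def compounds_to_frame(compounds: Iterable[CompoundParams]) -> pd.DataFrame:
    return pd.DataFrame([c.to_dict() for c in compounds], columns=COMPOUND_COLUMNS)


def frame_to_compounds(frame: pd.DataFrame) -> list[CompoundParams]:
    missing = set(COMPOUND_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    return [
        CompoundParams(**{name: float(row[name]) for name in COMPOUND_COLUMNS})
        for _, row in frame.iterrows()
    ]


def write_compounds_csv(compounds: Iterable[CompoundParams], path: str | Path) -> None:
    compounds_to_frame(compounds).to_csv(path, index=False)


def read_compounds_csv(path: str | Path) -> list[CompoundParams]:
    return frame_to_compounds(pd.read_csv(path))


def write_compound_yaml(compound: CompoundParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(compound.to_dict(), fh, sort_keys=False)


def read_compound_yaml(path: str | Path) -> CompoundParams:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    compound = CompoundParams(**{k: float(v) for k, v in data.items()})
    compound.validate()
    return compound
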