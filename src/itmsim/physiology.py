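"""Anatomical volumes and blood flows for the PBPK model.

All flows are in L/h and volumes in L, scaled allometrically from body
weight following the Davies & Morris reference-human convention; the
target tissue is a fixed 5 mL permeability-limited organ (solid-tumour
geometry) whose extracellular and intracellular sub-volumes and blood
flow do not scale with body weight.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace


@dataclass(frozen=True)
class PhysiologyParams:
    """Fixed physiology for one virtual subject.

    Attributes
    ----------
    weight : body mass (kg)
    Qa, Qh, Qm, Qs : blood flow to adipose / liver / muscle / skin (L/h)
    Qt : blood flow to the target tissue (L/h)
    Va, Vh, Vm, Vs : adipose / liver / muscle / skin volumes (L)
    Vhe : liver extracellular (sinusoidal + interstitial) space (L), < Vh
    Vt : target extracellular (interstitial + vascular) volume (L)
    Vt_ic : target intracellular volume (L)
    Vb : blood volume (L)
    """

    weight: float
    Qa: float
    Qh: float
    Qm: float
    Qs: float
    Qt: float
    Va: float
    Vh: float
    Vhe: float
    Vm: float
    Vs: float
    Vt: float
    Vt_ic: float
    Vb: float

    @property
    def Vh_ic(self) -> float:
        """Hepatocellular volume (L): total liver minus extracellular space."""
        return self.Vh - self.Vhe

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise ValueError(f"physiology field {name!r} must be > 0, got {value}")
        if not self.Vhe < self.Vh:
            raise ValueError("liver extracellular space Vhe must be smaller than Vh")
        if self.Vt + self.Vt_ic > 5.0e-3 + 1e-12:
            raise ValueError("target sub-volumes exceed the 5 mL organ volume")

    def replace(self, **changes) -> "PhysiologyParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhysiologyParams":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        phys = cls(**{k: float(v) for k, v in data.items()})
        phys.validate()
        return phys


#: Target tissue geometry: 5 mL organ; vascular + interstitial volume
#: fractions 0.204 and 0.296, perfusion 0.686 mL/min/mL tissue
#: (permeability-limited solid-tumour parameterisation).
_TARGET_ML = 5.0
_TARGET_EC_FRACTION = 0.204 + 0.296
_TARGET_PERFUSION_ML_MIN_ML = 0.686

#: Blood volume, mL/kg (Davies & Morris).
BLOOD_ML_PER_KG = 79.0


def build_physiology(weight: float = 75.0) -> PhysiologyParams:
    """Build the reference physiology for a subject of the given body weight.

    Flows use mL/min/kg coefficients times weight, converted to L/h;
    volumes use mL/kg coefficients. The 75 kg default reproduces the
    reference values used throughout the Monte Carlo study (for example
    Qh = 20.7*75*60/1000 = 93.15 L/h and Qt = 0.2058 L/h).
    """
    if not weight > 0:
        raise ValueError(f"body weight must be positive, got {weight}")
    phys = PhysiologyParams(
        weight=weight,
        Qa=3.72 * weight * 60 / 1000,
        Qh=20.7 * weight * 60 / 1000,
        Qm=10.7 * weight * 60 / 1000,
        Qs=4.28 * weight * 60 / 1000,
        Qt=_TARGET_PERFUSION_ML_MIN_ML * 60 / 1000 * _TARGET_ML,
        Va=142 * weight / 1000,
        Vh=17.4 * weight / 1000,
        Vhe=6.69 * weight / 1000,
        Vm=429 * weight / 1000,
        Vs=111 * weight / 1000,
        Vt=_TARGET_ML / 1000 * _TARGET_EC_FRACTION,
        Vt_ic=_TARGET_ML / 1000 * (1 - _TARGET_EC_FRACTION),
        Vb=BLOOD_ML_PER_KG * weight / 1000,
    )
    phys.validate()
    return phys
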