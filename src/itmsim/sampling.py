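"""Monte Carlo generation of virtual compound populations.

Every kinetic and binding parameter follows a log-normal distribution
specified by its interquartile range, emulating the spread observed
across marketed small molecules. Plasma protein binding, renal
clearance and the steady-state distribution volume are drawn jointly
from a multivariate log-normal: the binding ratio B = nPt/Kd,protein
(moles of protein binding sites over the protein dissociation constant)
gives the unbound fraction fub = 1/(1+B), and Vss sets the common
tissue-partition scaling factor.

Each parameter has its own named RNG substream so that adding a
parameter to the configuration never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import ks_2samp

from .compound import CompoundParams, KP_TISSUE_FACTORS, DEFAULT_MOLAR_MASS, compounds_to_frame
from .physiology import PhysiologyParams, build_physiology

__all__ = [
    "LogNormalSpec",
    "JointDistributionConfig",
    "GenerationConfig",
    "CompoundPopulation",
    "lognormal_from_iqr",
    "sample_compounds",
    "ecdf_compare",
    "kp_scaling_from_vss",
]

#: Quartile z-score: Phi^{-1}(0.75).
_Z75 = 0.67448975


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal law given by its median and the SD of the natural log."""

    median: float
    sigma_log: float

    def __post_init__(self):
        if not self.median > 0:
            raise ValueError("log-normal median must be positive")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")

    @property
    def iqr(self) -> tuple[float, float]:
        half = np.exp(_Z75 * self.sigma_log)
        return self.median / half, self.median * half

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sigma_log == 0.0:
            return np.full(n, self.median)
        return self.median * np.exp(self.sigma_log * rng.standard_normal(n))


def lognormal_from_iqr(q25: float, q75: float) -> LogNormalSpec:
    """Invert an interquartile range into a log-normal specification.

    The quartiles of a log-normal are median*exp(±z75*sigma), so
    median = sqrt(q25*q75) and sigma = ln(q75/median)/z75.
    """
    if not (0 < q25 <= q75):
        raise ValueError("require 0 < q25 <= q75")
    median = float(np.sqrt(q25 * q75))
    sigma = float(np.log(q75 / median) / _Z75)
    return LogNormalSpec(median=median, sigma_log=sigma)


#: Interquartile ranges of the independently sampled kinetic/binding
#: parameters (whole-body rates in µmol/h, Km in µM, PS in L/h,
#: Kd in µM, koff in 1/h, X_TotalR in µmol).
PARAMETER_IQRS: dict[str, tuple[float, float]] = {
    "Vmax_uptake": (10.0, 1000.0),
    "Km_uptake": (1.0 / 3.0, 3.0),
    "Vmax_met": (25.0, 2500.0),
    "Km_met": (10.0 / 3.0, 30.0),
    "PSdif_inf": (3.0, 300.0),
    "Vmax_targetUptake": (0.0192, 1.92),
    "Km_targetUptake": (1.0 / 3.0, 3.0),
    "PSdiff_target": (0.0115, 1.15),
    "Vmax_targetMet": (0.0192, 1.92),
    "Km_targetMet": (10.0 / 3.0, 30.0),
    "Kd": (3e-4, 6e-3),
    "koff": (0.25, 4.0),
    "X_TotalR": (1e-3, 0.1),
}

#: Floor applied to the tissue-partition scaling factor.
KP_SCALING_FLOOR = 0.01


@dataclass(frozen=True)
class JointDistributionConfig:
    """Correlated log-normal law for (B, CLr, Vss).

    The defaults are an approximate stand-in for the unpublished joint
    distribution of protein binding, renal clearance and distribution
    volume across marketed drugs: B median 1 (fub median 0.5), CLr
    median 3 L/h, Vss median 50 L, independent on the log scale.
    """

    B: LogNormalSpec = LogNormalSpec(1.0, 1.5)
    CLr: LogNormalSpec = LogNormalSpec(3.0, 1.5)
    Vss: LogNormalSpec = LogNormalSpec(50.0, 1.0)
    correlation: tuple = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )

    def correlation_matrix(self) -> np.ndarray:
        m = np.asarray(self.correlation, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("correlation must be a 3x3 matrix")
        if not np.allclose(m, m.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(m).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")
        return m

    def sample(self, rng: np.random.Generator, n: int) -> pd.DataFrame:
        corr = self.correlation_matrix()
        sigmas = np.array([self.B.sigma_log, self.CLr.sigma_log, self.Vss.sigma_log])
        medians = np.array([self.B.median, self.CLr.median, self.Vss.median])
        cov = corr * np.outer(sigmas, sigmas)
        z = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
        values = medians * np.exp(z)
        return pd.DataFrame(values, columns=["B", "CLr", "Vss"])


@dataclass(frozen=True)
class GenerationConfig:
    """Full recipe for one virtual compound population."""

    iqrs: dict = field(default_factory=lambda: dict(PARAMETER_IQRS))
    joint: JointDistributionConfig = field(default_factory=JointDistributionConfig)
    molar_mass: float = DEFAULT_MOLAR_MASS

    def specs(self) -> dict[str, LogNormalSpec]:
        return {name: lognormal_from_iqr(*iqr) for name, iqr in self.iqrs.items()}

    def to_dict(self) -> dict:
        return {
            "iqrs": {k: list(v) for k, v in self.iqrs.items()},
            "joint": asdict(self.joint),
            "molar_mass": self.molar_mass,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GenerationConfig":
        joint = data.get("joint", {})
        jd = JointDistributionConfig(
            B=LogNormalSpec(**joint.get("B", {"median": 1.0, "sigma_log": 1.5})),
            CLr=LogNormalSpec(**joint.get("CLr", {"median": 3.0, "sigma_log": 1.5})),
            Vss=LogNormalSpec(**joint.get("Vss", {"median": 50.0, "sigma_log": 1.0})),
            correlation=tuple(map(tuple, joint.get("correlation", np.eye(3).tolist()))),
        )
        jd.correlation_matrix()
        return cls(
            iqrs={k: tuple(v) for k, v in data.get("iqrs", PARAMETER_IQRS).items()},
            joint=jd,
            molar_mass=float(data.get("molar_mass", DEFAULT_MOLAR_MASS)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenerationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class CompoundPopulation:
    """A reproducible sampled population of virtual compounds."""

    compounds: list[CompoundParams]
    seed: int
    config: GenerationConfig

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    def to_frame(self) -> pd.DataFrame:
        return compounds_to_frame(self.compounds)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent RNG substream."""
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


def kp_scaling_from_vss(
    vss: np.ndarray | float, physiology: PhysiologyParams
) -> np.ndarray | float:
    """Back out the Kp scaling factor from a steady-state volume.

    Vss = Vb + sum_i Kp_i*V_i over the flow-limited tissues with
    Kp_i = f_i*Kp_scaling, hence
    Kp_scaling = (Vss - Vb) / (0.1*Va + 0.2*Vm + 0.5*Vs), floored at
    0.01 so that partition coefficients stay positive when Vss < Vb.
    """
    denom = (
        KP_TISSUE_FACTORS["Kpa"] * physiology.Va
        + KP_TISSUE_FACTORS["Kpm"] * physiology.Vm
        + KP_TISSUE_FACTORS["Kps"] * physiology.Vs
    )
    return np.maximum((vss - physiology.Vb) / denom, KP_SCALING_FLOOR)


def sample_compounds(
    n: int,
    seed: int,
    config: GenerationConfig | None = None,
    physiology: PhysiologyParams | None = None,
) -> CompoundPopulation:
    """Draw ``n`` virtual compounds (bit-for-bit reproducible per seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or GenerationConfig()
    physiology = physiology or build_physiology()

    columns: dict[str, np.ndarray] = {}
    for name, spec in config.specs().items():
        columns[name] = spec.sample(_substream(seed, name), n)

    joint = config.joint.sample(_substream(seed, "joint"), n)
    fub = 1.0 / (1.0 + joint["B"].to_numpy())
    kp_scaling = kp_scaling_from_vss(joint["Vss"].to_numpy(), physiology)

    compounds = []
    for i in range(n):
        kwargs = {name: float(columns[name][i]) for name in columns}
        compounds.append(
            CompoundParams(
                **kwargs,
                fub=float(fub[i]),
                CLr=float(joint["CLr"].iloc[i]),
                Kp_scaling=float(kp_scaling[i]),
                Kpa=KP_TISSUE_FACTORS["Kpa"] * float(kp_scaling[i]),
                Kpm=KP_TISSUE_FACTORS["Kpm"] * float(kp_scaling[i]),
                Kps=KP_TISSUE_FACTORS["Kps"] * float(kp_scaling[i]),
                molar_mass=config.molar_mass,
            )
        )
    return CompoundPopulation(compounds=compounds, seed=seed, config=config)


#: Parameters accepted in user-supplied reference CSVs.
REFERENCE_PARAMETERS = ("Kd_uM", "koff_per_h", "fu", "CL_L_per_h", "bioavailable_dose_mg")


def read_reference_csv(path: str | Path, parameter: str) -> np.ndarray:
    """Load one parameter column from a ``compound,value,parameter`` CSV."""
    frame = pd.read_csv(path)
    required = {"compound", "value", "parameter"}
    if not required.issubset(frame.columns):
        raise ValueError(f"reference CSV must have columns {sorted(required)}")
    values = frame.loc[frame["parameter"] == parameter, "value"].to_numpy(float)
    if values.size == 0:
        raise ValueError(
            f"no rows for parameter {parameter!r}; reference lists are "
            "user-supplied (they are not bundled with the package)"
        )
    return values


def ecdf_compare(
    samples: Sequence[float], reference: Sequence[float]
) -> tuple[pd.DataFrame, float]:
    """Paired ECDFs on the merged support plus the Kolmogorov–Smirnov distance.

    Returns a plotting-ready table with columns ``value``,
    ``ecdf_samples`` and ``ecdf_reference``, and the two-sample KS
    statistic sup |F_samples - F_reference|.
    """
    samples = np.asarray(samples, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if samples.size == 0 or reference.size == 0:
        raise ValueError(
            "both inputs must be non-empty; reference lists are user-supplied"
        )
    support = np.unique(np.concatenate([samples, reference]))
    table = pd.DataFrame(
        {
            "value": support,
            "ecdf_samples": np.searchsorted(np.sort(samples), support, side="right")
            / samples.size,
            "ecdf_reference": np.searchsorted(np.sort(reference), support, side="right")
            / reference.size,
        }
    )
    ks = float(ks_2samp(samples, reference, method="asymp").statistic)
    return table, ks
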