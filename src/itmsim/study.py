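"""Study-level Monte Carlo analyses.

Runs the per-compound ITM procedure over a sampled population and
summarises it the way the feasibility study reports results: an overall
success probability with a Wilson 95% confidence interval, decile
subgroup tables for post-hoc covariates (estimated therapeutic dose,
hepatic clearance, target-tissue clearance), fixed-value sweeps of the
parameters that enter the simulation directly (Qt, Kd, X_TotalR), and a
sweep of the required occupancy level.

Subgroup analyses are pure post-processing of the per-compound results
table — they never re-simulate. Compounds whose dose search failed or
whose solver did not converge are excluded from every denominator and
reported separately.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .compound import COMPOUND_COLUMNS
from .physiology import PhysiologyParams, build_physiology
from .sampling import GenerationConfig, sample_compounds
from .trial import TrialConfig, evaluate_compound

__all__ = [
    "StudySummary",
    "SubgroupTable",
    "SweepTable",
    "run_study",
    "success_probability",
    "decile_subgroups",
    "parameter_sweep",
    "ro_threshold_sweep",
    "SUBGROUP_VARIABLES",
]

#: Post-hoc subgroup covariates and their results-table columns.
SUBGROUP_VARIABLES = {
    "therapeutic_dose": "therapeutic_dose_umol",
    "CLh": "CLh",
    "CL_target": "CL_target",
}


@dataclass
class StudySummary:
    """Aggregate outcome of one Monte Carlo ITM study."""

    n_compounds: int
    n_evaluated: int
    n_achievable: int
    n_success: int
    success_probability: float
    ci_low: float
    ci_high: float
    seed: int
    results: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "n_compounds": self.n_compounds,
            "n_evaluated": self.n_evaluated,
            "n_achievable": self.n_achievable,
            "n_success": self.n_success,
            "success_probability": self.success_probability,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "seed": self.seed,
        }


@dataclass
class SubgroupTable:
    """Per-decile success probabilities for one covariate."""

    variable: str
    table: pd.DataFrame

    def __post_init__(self):
        assert list(self.table.columns)[:1] == ["bin"]


@dataclass
class SweepTable:
    """Success probability at each fixed value of a swept parameter."""

    parameter: str
    table: pd.DataFrame


def analysis_mask(results: pd.DataFrame) -> pd.Series:
    """Compounds entering success denominators: solver converged and the
    therapeutic dose was achievable. Sentinel compounds are reported
    separately, never counted as failures."""
    return (~results["solver_failed"]) & np.isfinite(results["therapeutic_dose_umol"])


def success_probability(
    results: pd.DataFrame, predicate: Callable[[pd.DataFrame], pd.Series] | None = None
) -> tuple[float, tuple[float, float], int]:
    """Success fraction with a Wilson 95% CI over the evaluated compounds.

    ``predicate`` (a boolean mask function on the results table) selects
    a subgroup; the denominator is the evaluated, achievable compounds
    inside it.
    """
    mask = analysis_mask(results)
    if predicate is not None:
        mask &= predicate(results).fillna(False).astype(bool)
    sub = results.loc[mask]
    n = len(sub)
    if n == 0:
        raise ValueError("success probability undefined on an empty subgroup")
    k = int(sub["itm_success"].sum())
    low, high = proportion_confint(k, n, alpha=0.05, method="wilson")
    return k / n, (float(low), float(high)), n


def _evaluate_population(compounds, physiology, trial_config) -> pd.DataFrame:
    rows = []
    for i, compound in enumerate(compounds):
        result = evaluate_compound(compound, physiology, trial_config, compound_id=i)
        row = result.to_row()
        row.update(compound.to_dict())
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame["itm_success"] = frame["itm_success"].astype(bool)
    frame["solver_failed"] = frame["solver_failed"].astype(bool)
    return frame


def run_study(
    n: int,
    seed: int,
    trial_config: TrialConfig | None = None,
    generation_config: GenerationConfig | None = None,
    physiology: PhysiologyParams | None = None,
) -> StudySummary:
    """Sample ``n`` virtual compounds, run the ITM procedure on each.

    Fully reproducible given ``seed``: sampling uses named per-parameter
    substreams and the per-compound evaluation is deterministic.
    """
    trial_config = trial_config or TrialConfig()
    generation_config = generation_config or GenerationConfig()
    physiology = physiology or build_physiology()

    population = sample_compounds(n, seed, generation_config, physiology)
    results = _evaluate_population(population, physiology, trial_config)

    evaluated = results.loc[~results["solver_failed"]]
    analysed = results.loc[analysis_mask(results)]
    n_success = int(analysed["itm_success"].sum())
    if len(analysed):
        p, (lo, hi), _ = success_probability(results)
    else:
        p, lo, hi = math.nan, math.nan, math.nan
    return StudySummary(
        n_compounds=n,
        n_evaluated=len(evaluated),
        n_achievable=len(analysed),
        n_success=n_success,
        success_probability=p,
        ci_low=lo,
        ci_high=hi,
        seed=seed,
        results=results,
    )


def decile_subgroups(results: pd.DataFrame, variable: str) -> SubgroupTable:
    """Split evaluated compounds into 10 equal-count bins of a covariate.

    Ties and bin sizes: stable sort by (variable, compound id); bins get
    ⌊n/10⌋ or ⌈n/10⌉ members so the bins partition the evaluated set.
    """
    column = SUBGROUP_VARIABLES.get(variable, variable)
    if column not in results.columns:
        raise ValueError(f"unknown subgroup variable {variable!r}")
    evaluated = results.loc[analysis_mask(results)]
    if len(evaluated) < 10:
        raise ValueError("need at least 10 evaluated compounds for deciles")
    ordered = evaluated.sort_values([column, "id"], kind="stable")
    chunks = np.array_split(np.arange(len(ordered)), 10)
    rows = []
    for b, idx in enumerate(chunks):
        part = ordered.iloc[idx]
        k, n = int(part["itm_success"].sum()), len(part)
        low, high = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append(
            {
                "bin": b + 1,
                "lower": float(part[column].iloc[0]),
                "upper": float(part[column].iloc[-1]),
                "n": n,
                "n_success": k,
                "success_probability": k / n,
                "ci_low": float(low),
                "ci_high": float(high),
            }
        )
    return SubgroupTable(variable=variable, table=pd.DataFrame(rows))


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


def _pin_parameter(compound, parameter, value):
    changes = {parameter: value}
    if parameter == "Kd":
        # kon = koff/Kd is derived, nothing else to update
        pass
    return compound.replace(**changes)


def parameter_sweep(
    parameter: str,
    values: Sequence[float],
    n_per_value: int,
    seed: int,
    trial_config: TrialConfig | None = None,
    generation_config: GenerationConfig | None = None,
    physiology: PhysiologyParams | None = None,
) -> SweepTable:
    """Fix one model parameter at each value, resampling everything else.

    ``parameter`` is a compound parameter (``Kd``, ``X_TotalR``, ...)
    or the target blood flow ``Qt``. Each value gets an independent
    population of ``n_per_value`` compounds.
    """
    trial_config = trial_config or TrialConfig()
    generation_config = generation_config or GenerationConfig()
    physiology = physiology or build_physiology()

    rows = []
    for i, value in enumerate(values):
        sub_seed = _child_seed(seed, i)
        population = sample_compounds(n_per_value, sub_seed, generation_config, physiology)
        if parameter == "Qt":
            phys_i = physiology.replace(Qt=float(value))
            compounds = list(population)
        else:
            phys_i = physiology
            compounds = [_pin_parameter(c, parameter, float(value)) for c in population]
        results = _evaluate_population(compounds, phys_i, trial_config)
        p, (lo, hi), n_eval = success_probability(results)
        rows.append(
            {
                "value": float(value),
                "n": n_per_value,
                "n_evaluated": n_eval,
                "success_probability": p,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return SweepTable(parameter=parameter, table=pd.DataFrame(rows))


def default_sweep_values(
    parameter: str,
    generation_config: GenerationConfig | None = None,
    physiology: PhysiologyParams | None = None,
    n_values: int = 7,
) -> np.ndarray:
    """Seven log-spaced values spanning the parameter's 1st–99th percentiles."""
    generation_config = generation_config or GenerationConfig()
    physiology = physiology or build_physiology()
    from scipy.stats import norm

    if parameter == "Qt":
        q = physiology.Qt
        return np.geomspace(q / 30, q * 30, n_values)
    spec = generation_config.specs()[parameter]
    z = norm.ppf(0.99)
    lo = spec.median * np.exp(-z * spec.sigma_log)
    hi = spec.median * np.exp(z * spec.sigma_log)
    return np.geomspace(lo, hi, n_values)


def ro_threshold_sweep(
    thresholds: Sequence[float],
    n: int,
    seed: int,
    trial_config: TrialConfig | None = None,
    generation_config: GenerationConfig | None = None,
    physiology: PhysiologyParams | None = None,
) -> pd.DataFrame:
    """Success probability versus the required occupancy level.

    The estimated therapeutic dose depends on the threshold, so dose
    finding and the ITM simulation are re-run per threshold on one
    shared compound population.
    """
    trial_config = trial_config or TrialConfig()
    generation_config = generation_config or GenerationConfig()
    physiology = physiology or build_physiology()
    for t in thresholds:
        if not (0 < t < 1):
            raise ValueError("thresholds must lie strictly between 0 and 1")

    population = sample_compounds(n, seed, generation_config, physiology)
    rows = []
    for threshold in thresholds:
        config_t = trial_config.replace(target_avg_ro=float(threshold))
        results = _evaluate_population(population, physiology, config_t)
        p, (lo, hi), n_eval = success_probability(results)
        rows.append(
            {
                "required_avg_ro": float(threshold),
                "n_evaluated": n_eval,
                "success_probability": p,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def write_study_outputs(
    summary: StudySummary,
    out_dir: str | Path,
    config_hash: str | None = None,
    subgroup_variables: Sequence[str] = ("therapeutic_dose", "CLh", "CL_target"),
) -> None:
    """Write study_results.csv, summary.json and subgroup tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.results.to_csv(out / "study_results.csv", index=False)
    payload = summary.to_dict()
    if config_hash is not None:
        payload["config_hash"] = config_hash
    with open(out / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    for variable in subgroup_variables:
        try:
            table = decile_subgroups(summary.results, variable)
        except ValueError:
            continue
        table.table.to_csv(out / f"subgroups_{variable}.csv", index=False)
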