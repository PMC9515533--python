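"""Synthetic study-like cohorts and model-simulated trough observations.

The clinical TDM records behind the published model are not deposited, so
estimation, diagnostics and bootstrap are exercised on synthetic cohorts that
emulate the study population: 24 children (16 boys / 8 girls), weight
median 22 kg within 10-63 kg, ages 2.15-17.92 years, routine laboratory
covariates at the reported means/SDs/ranges, and comedication counts
11 (cefdinir), 4 (omeprazole), 2 (posaconazole), 12 (sulfamethoxazole).

Lab covariates are generated as independent truncated normals (no correlation
structure is reported for the real cohort; independence suffices for
exercising a null covariate search).  Weight and age are truncated lognormals
matched to the reported medians and ranges.

The default observation design mirrors therapy-initiation TDM: once-daily
oral dosing at 0.06 mg/kg/day with trough samples on days 3, 7 and 28 after
the first dose.  The early troughs sit on the accumulation phase and are what
make the apparent volume identifiable from trough-only data; with
steady-state-only sampling the trough is almost insensitive to V/F and only
clearance can be recovered.  Observations are computed by exact superposition
of all administered doses (no steady-state approximation), then perturbed by
the true residual model; additive residuals are redrawn until the recorded
concentration is positive, since trough assays report positive values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import Dataset, Subject
from .errors import ConfigError
from .estimate import _Compiled, _predict, _tv_arrays
from .popmodel import PopulationModel, apply_residual

#: Table-style lab covariate targets: name -> (mean, sd, low, high)
DEFAULT_LABS: dict[str, tuple[float, float, float, float]] = {
    "ALB": (40.17, 5.52, 26.10, 50.20),
    "ALT": (15.71, 6.16, 2.82, 28.60),
    "AST": (28.31, 8.95, 15.20, 51.50),
    "CREA": (31.06, 10.78, 17.00, 58.00),
    "UREA": (3.82, 0.98, 2.60, 6.70),
    "TP": (70.67, 7.36, 55.80, 87.30),
    "TBA": (6.35, 4.12, 0.90, 13.70),
    "DBIL": (2.79, 1.42, 0.80, 6.30),
    "TBIL": (8.79, 3.89, 2.90, 16.60),
    "HCT": (35.96, 6.80, 24.20, 50.50),
    "HGB": (116.67, 24.72, 71.00, 166.00),
    "MCH": (25.77, 2.80, 18.70, 28.60),
    "MCHC": (323.58, 24.58, 273.00, 364.00),
}

#: study comedication prevalences (counts out of 24)
DEFAULT_COMEDS: dict[str, float] = {
    "CEF": 11 / 24,
    "OME": 4 / 24,
    "POS": 2 / 24,
    "SMZ": 12 / 24,
}


@dataclass(frozen=True)
class CohortSpec:
    """Demographic/covariate targets for a synthetic cohort."""

    n: int = 24
    weight_median: float = 22.0
    weight_log_sd: float = 0.32
    weight_range: tuple[float, float] = (10.0, 63.0)
    age_median: float = 7.94
    age_log_sd: float = 0.45
    age_range: tuple[float, float] = (2.15, 17.92)
    female_prevalence: float = 8 / 24  # SEX: 0 = boy, 1 = girl
    comed_prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMEDS))
    labs: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LABS)
    )
    exact_counts: bool = True  # assign comedications/sex by exact expected counts

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError("cohort needs n >= 2")
        for name, p in self.comed_prevalence.items():
            if not 0 <= p <= 1:
                raise ConfigError(f"prevalence of {name} must be in [0, 1]")
        if not self.weight_range[0] < self.weight_range[1]:
            raise ConfigError("weight_range must be increasing")
        if not (self.weight_range[0] <= self.weight_median <= self.weight_range[1]):
            raise ConfigError("weight median outside truncation range")


@dataclass(frozen=True)
class ObservationDesign:
    """Once-daily TDM design: dose rate and trough-sampling days."""

    dose_per_kg: float = 0.06  # mg/kg/day
    trough_days: tuple[int, ...] = (3, 7, 28)
    tau: float = 24.0

    def __post_init__(self) -> None:
        if self.dose_per_kg <= 0:
            raise ConfigError("dose_per_kg must be > 0")
        if not self.trough_days or any(d < 1 for d in self.trough_days):
            raise ConfigError("trough_days must be >= 1")
        if self.tau <= 0:
            raise ConfigError("tau must be > 0")


def _truncated_lognormal(rng, median, log_sd, lo, hi, size):
    a = (math.log(lo) - math.log(median)) / log_sd
    b = (math.log(hi) - math.log(median)) / log_sd
    z = stats.truncnorm.rvs(a, b, size=size, random_state=rng)
    return np.exp(math.log(median) + log_sd * z)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _assign_flags(rng, n, prevalence, exact):
    if exact:
        count = int(round(prevalence * n))
        flags = np.zeros(n)
        flags[rng.permutation(n)[:count]] = 1.0
        return flags
    return (rng.random(n) < prevalence).astype(float)


def generate_cohort(spec: CohortSpec, seed) -> Dataset:
    """Reproducible covariate-only cohort (no dose events or observations)."""
    rng = np.random.default_rng(seed)
    n = spec.n
    weights = _truncated_lognormal(
        rng, spec.weight_median, spec.weight_log_sd, *spec.weight_range, size=n
    )
    ages = _truncated_lognormal(rng, spec.age_median, spec.age_log_sd, *spec.age_range, size=n)
    sex = _assign_flags(rng, n, spec.female_prevalence, spec.exact_counts)
    comeds = {
        name: _assign_flags(rng, n, p, spec.exact_counts)
        for name, p in spec.comed_prevalence.items()
    }
    labs = {
        name: _truncated_normal(rng, *params, size=n) for name, params in spec.labs.items()
    }
    subjects = []
    for i in range(n):
        covs = {"SEX": float(sex[i]), "AGE": float(ages[i])}
        covs.update({name: float(vals[i]) for name, vals in comeds.items()})
        covs.update({name: float(vals[i]) for name, vals in labs.items()})
        subjects.append(Subject(id=i + 1, weight=float(weights[i]), covariates=covs))
    return Dataset(subjects)


def simulate_observations(
    cohort: Dataset,
    true_model: PopulationModel,
    design: ObservationDesign | None = None,
    seed=0,
) -> Dataset:
    """Attach once-daily dosing and model-simulated trough observations.

    Each subject receives daily doses from day 0 through the last trough day
    minus one; troughs are sampled at ``day * tau`` hours, immediately before
    the next dose.  Concentrations come from exact Bateman superposition at
    the subject's individual parameters, perturbed by the true residual model
    (redrawn until positive).
    """
    design = design or ObservationDesign()
    rng = np.random.default_rng(seed)
    last_day = max(design.trough_days)

    dosed = Dataset([s.copy() for s in cohort.subjects])
    for s in dosed.subjects:
        amount = design.dose_per_kg * s.weight * 1000.0  # ug
        s.doses = [(day * design.tau, amount) for day in range(last_day)]
        s.observations = [(day * design.tau, 1.0) for day in design.trough_days]

    c = _Compiled(dosed)
    tvcl, tvv, ka = _tv_arrays(true_model, c)
    eta = rng.normal(0.0, true_model.iiv.sd, size=c.n_sub)
    f, ok = _predict(c, tvcl, tvv, ka, eta)
    if not ok.all():
        raise ConfigError("degenerate kinetics for some simulated subjects")

    spec = true_model.residual
    obs_idx = 0
    for s in dosed.subjects:
        new_obs = []
        for t, _ in s.observations:
            pred = float(f[obs_idx])
            for _attempt in range(1000):
                eps1 = rng.normal(0.0, spec.sd1)
                eps2 = rng.normal(0.0, spec.sd2) if spec.kind == "mixed" else 0.0
                y = apply_residual(pred, eps1, eps2, spec)
                if y > 0 or (spec.sd1 == 0 and spec.sd2 == 0):
                    break
            if y <= 0:
                y = pred  # unreachable in practice; documented fallback
            new_obs.append((t, float(y)))
            obs_idx += 1
        s.observations = new_obs
    dosed.validate()
    return dosed
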