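"""Monte Carlo simulation of steady-state troughs and initial-dose selection.

Virtual patients are drawn from the population model's lognormal clearance
distribution; each patient's once-daily steady-state trough is evaluated with
the closed-form accumulation formula.  The probability of a trough inside the
therapeutic window (5-15 ng/ml, inclusive) drives the dose recommendation;
the probability of exceeding the 15 ng/ml upper limit is the safety summary.

The simulated endpoint excludes residual (assay) error by default: the
additive residual SD of the final model largely reflects measurement noise
rather than true exposure, and the decision quantity is the patient's actual
steady-state trough.  ``include_residual=True`` restores it.

Within an arm (one weight, one comedication state) the same random effects
are reused across all candidate doses (common random numbers): troughs are
linear in dose, so this both reduces Monte Carlo variance of dose contrasts
and makes exceedance probabilities exactly non-decreasing in dose.  Arm-level
generators derive from the master seed and the arm labels via
``numpy.random.SeedSequence([seed, round(1000*weight), pos])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, NoFeasibleDoseError
from .pk import steady_state_trough_array
from .popmodel import PopulationModel, typical_params

DEFAULT_WEIGHTS = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0)
DEFAULT_DOSES = tuple(round(0.01 * k, 2) for k in range(1, 11))  # mg/kg/day


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario for the simulation grid and dose recommendation."""

    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    doses: tuple[float, ...] = DEFAULT_DOSES  # mg/kg/day
    n: int = 1000
    tau: float = 24.0
    window: tuple[float, float] = (5.0, 15.0)
    include_residual: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if not self.window[0] < self.window[1]:
            raise ConfigError("window lower bound must be below upper bound")
        if any(d <= 0 for d in self.doses) or not self.doses:
            raise ConfigError("doses must be positive")
        if any(w <= 0 for w in self.weights) or not self.weights:
            raise ConfigError("weights must be positive")
        if self.tau <= 0:
            raise ConfigError("tau must be > 0")


def _arm_rng(seed: int, weight: float, pos: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(round(1000 * weight)), int(pos)])
    )


def simulate_troughs(
    model: PopulationModel,
    weight: float,
    dose_per_kg: float,
    pos: int = 0,
    n: int = 1000,
    seed=0,
    include_residual: bool = False,
    tau: float = 24.0,
) -> np.ndarray:
    """Steady-state troughs (ng/ml) of ``n`` virtual patients.

    ``dose_per_kg`` is in mg/kg/day; the administered dose is
    ``dose_per_kg * weight`` mg once daily.  ``seed`` may be an int,
    SeedSequence or Generator.
    """
    if weight <= 0 or dose_per_kg <= 0 or n < 1:
        raise ConfigError("weight, dose_per_kg must be > 0 and n >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    typ = typical_params(model, weight, pos=pos)
    eta = rng.normal(0.0, model.iiv.sd, size=n)
    cl = typ.cl * np.exp(eta)
    dose_ug = dose_per_kg * weight * 1000.0
    troughs = steady_state_trough_array(dose_ug, cl, typ.v, typ.ka, tau)
    if include_residual:
        eps = rng.normal(0.0, model.residual.sd1, size=n)
        troughs = np.maximum(troughs + eps, 0.0)
    return troughs


def pta(troughs, window=(5.0, 15.0)) -> float:
    """Fraction of troughs inside the inclusive target window."""
    t = np.asarray(troughs, dtype=float)
    if t.size == 0:
        raise ConfigError("empty trough vector")
    lo, hi = window
    return float(np.mean((t >= lo) & (t <= hi)))


def p_exceed(troughs, upper: float = 15.0) -> float:
    """Fraction of troughs strictly above the upper safety limit."""
    t = np.asarray(troughs, dtype=float)
    if t.size == 0:
        raise ConfigError("empty trough vector")
    return float(np.mean(t > upper))


def _arm_troughs_by_dose(model, weight, pos, config: SimulationConfig) -> dict[float, np.ndarray]:
    """Troughs for every candidate dose, sharing one set of random draws."""
    rng = _arm_rng(config.seed, weight, pos)
    eta = rng.normal(0.0, model.iiv.sd, size=config.n)
    typ = typical_params(model, weight, pos=pos)
    cl = typ.cl * np.exp(eta)
    unit = steady_state_trough_array(1.0, cl, typ.v, typ.ka, config.tau)  # per ug
    eps = rng.normal(0.0, model.residual.sd1, size=config.n) if config.include_residual else None
    out = {}
    for dose in config.doses:
        t = dose * weight * 1000.0 * unit
        if eps is not None:
            t = np.maximum(t + eps, 0.0)
        out[dose] = t
    return out


def recommend_dose(
    model: PopulationModel,
    weight: float,
    pos: int = 0,
    config: SimulationConfig | None = None,
) -> float:
    """Candidate dose (mg/kg/day) maximizing the probability of target attainment.

    Ties break toward the lower dose.  Raises :class:`NoFeasibleDoseError`
    when no candidate dose ever reaches the window.
    """
    config = config or SimulationConfig()
    by_dose = _arm_troughs_by_dose(model, weight, pos, config)
    doses = sorted(by_dose)
    ptas = np.array([pta(by_dose[d], config.window) for d in doses])
    if ptas.max() == 0.0:
        raise NoFeasibleDoseError(
            f"no dose on the grid attains {config.window} ng/ml at {weight} kg (POS={pos})"
        )
    return float(doses[int(np.argmax(ptas))])  # argmax returns first (lowest) on ties


def simulate_grid(model: PopulationModel, config: SimulationConfig | None = None,
                  pos_values=(0, 1)) -> pd.DataFrame:
    """Full weight x dose x comedication grid: median trough, PTA, P(exceed)."""
    config = config or SimulationConfig()
    rows = []
    for pos in pos_values:
        for weight in config.weights:
            by_dose = _arm_troughs_by_dose(model, weight, pos, config)
            for dose in config.doses:
                t = by_dose[dose]
                rows.append(
                    {
                        "weight_kg": weight,
                        "dose_mg_per_kg_day": dose,
                        "pos": pos,
                        "median_trough_ng_ml": float(np.median(t)),
                        "pta": pta(t, config.window),
                        "p_exceed": p_exceed(t, config.window[1]),
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DoseRecommendation:
    """One weight band of the initial-dose table (half-open [low, high) kg)."""

    weight_low: float
    weight_high: float
    dose_per_kg: float  # mg/kg/day
    pta: float  # lowest PTA across the band's evaluated weights


def weight_band_table(
    model: PopulationModel,
    config: SimulationConfig | None = None,
    pos: int = 0,
    weight_range: tuple[float, float] = (10.0, 60.0),
    weight_step: float = 1.0,
) -> list[DoseRecommendation]:
    """Initial-dose bands from a fine weight grid.

    ``recommend_dose`` runs at every grid weight; contiguous weights sharing a
    recommendation merge into bands that tile [low, high] without gaps.
    """
    config = config or SimulationConfig()
    lo, hi = weight_range
    if not (lo < hi):
        raise ConfigError("weight_range must be increasing")
    grid = np.arange(lo, hi + 0.5 * weight_step, weight_step)
    recs, ptas = [], []
    for w in grid:
        by_dose = _arm_troughs_by_dose(model, float(w), pos, config)
        doses = sorted(by_dose)
        vals = np.array([pta(by_dose[d], config.window) for d in doses])
        if vals.max() == 0.0:
            raise NoFeasibleDoseError(f"no feasible dose at {w} kg (POS={pos})")
        best = int(np.argmax(vals))
        recs.append(doses[best])
        ptas.append(vals[best])

    bands: list[DoseRecommendation] = []
    start = 0
    for i in range(1, len(grid) + 1):
        if i == len(grid) or recs[i] != recs[start]:
            bands.append(
                DoseRecommendation(
                    weight_low=float(grid[start]),
                    weight_high=float(grid[i - 1]) if i == len(grid) else float(grid[i]),
                    dose_per_kg=float(recs[start]),
                    pta=float(min(ptas[start:i])),
                )
            )
            start = i
    return bands


def band_table_frame(bands) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "weight_low_kg": b.weight_low,
                "weight_high_kg": b.weight_high,
                "dose_mg_per_kg_day": b.dose_per_kg,
                "min_pta": b.pta,
            }
            for b in bands
        ]
    )
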