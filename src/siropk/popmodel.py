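"""Population model: covariate structure, inter-individual and residual variability.

The model follows the standard nonlinear mixed-effects decomposition used in
pediatric pharmacometrics:

* fixed allometric weight scaling to a 70 kg reference
  (``CL/F ~ (WT/70)^0.75``, ``V/F ~ (WT/70)^1``);
* additional covariate effects on a typical parameter, either the power form
  on the covariate's population median (continuous covariates) or the
  linear-proportional form ``TV * (1 + theta * Cov)`` (categorical 0/1
  covariates);
* a single lognormal random effect on clearance,
  ``CL_i = TVCL * exp(eta_i)`` with ``eta_i ~ N(0, omega^2)``;
* a residual error model on observed concentrations that is additive,
  proportional, or mixed.

The published sirolimus model is available as :func:`sirolimus_final_model`:
``CL/F = 10.4 * (WT/70)^0.75 * (1 - 0.762*POS)`` L/h,
``V/F = 583 * (WT/70)`` L, ``Ka`` fixed at 0.485 1/h, ``omega_CL = 0.303``
(SD of eta), additive residual SD 3.674 ng/ml.  Whether the reported
variability terms are SDs or variances is ambiguous in such tables; the SD
reading is the default, with ``as_variance`` switches to adopt the other.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError, InvalidCovariateError, InvalidParameterError
from .pk import StructuralParams

RESIDUAL_KINDS = ("additive", "proportional", "mixed")


@dataclass(frozen=True)
class ThetaVector:
    """Typical structural parameters at the reference weight."""

    cl: float  # L/h at the 70 kg reference
    v: float  # L at the 70 kg reference
    ka: float  # 1/h
    ka_fixed: bool = True

    def __post_init__(self) -> None:
        for name in ("cl", "v", "ka"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise InvalidParameterError(f"theta.{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class AllometrySpec:
    """Fixed allometric exponents; not estimated."""

    standard_weight: float = 70.0
    exponent_cl: float = 0.75
    exponent_v: float = 1.0

    def __post_init__(self) -> None:
        if self.standard_weight <= 0:
            raise InvalidParameterError("standard_weight must be > 0")


@dataclass(frozen=True)
class RandomEffectSpec:
    """Lognormal inter-individual variability on CL/F."""

    omega_cl: float
    as_variance: bool = False

    def __post_init__(self) -> None:
        if self.omega_cl < 0:
            raise InvalidParameterError("omega_cl must be >= 0")

    @property
    def sd(self) -> float:
        """Standard deviation of eta on log-clearance."""
        return math.sqrt(self.omega_cl) if self.as_variance else self.omega_cl


@dataclass(frozen=True)
class ResidualSpec:
    """Residual unexplained variability on observed concentrations."""

    kind: str = "additive"
    sigma1: float = 0.0
    sigma2: float | None = None
    as_variance: bool = False

    def __post_init__(self) -> None:
        if self.kind not in RESIDUAL_KINDS:
            raise ConfigError(f"unknown residual kind {self.kind!r}; expected one of {RESIDUAL_KINDS}")
        if self.sigma1 < 0:
            raise InvalidParameterError("sigma1 must be >= 0")
        if self.kind == "mixed":
            if self.sigma2 is None or self.sigma2 < 0:
                raise InvalidParameterError("mixed residual model requires sigma2 >= 0")
        elif self.sigma2 is not None:
            raise ConfigError("sigma2 is only meaningful for the mixed residual model")

    @property
    def sd1(self) -> float:
        return math.sqrt(self.sigma1) if self.as_variance else self.sigma1

    @property
    def sd2(self) -> float:
        if self.sigma2 is None:
            return 0.0
        return math.sqrt(self.sigma2) if self.as_variance else self.sigma2

    def variance(self, pred):
        """Residual variance g^2 evaluated at prediction(s) ``pred``."""
        if self.kind == "additive":
            return self.sd1**2 + 0.0 * pred
        if self.kind == "proportional":
            return (self.sd1 * pred) ** 2
        return (self.sd1 * pred) ** 2 + self.sd2**2


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate effect on a typical parameter.

    ``form="power"`` is the continuous form ``TV * (Cov/median)^theta``;
    ``form="linear"`` is the categorical form ``TV * (1 + theta*Cov)``.
    """

    target: str  # "cl" or "v"
    name: str
    form: str  # "power" or "linear"
    theta: float
    median: float | None = None

    def __post_init__(self) -> None:
        if self.target not in ("cl", "v"):
            raise ConfigError(f"effect target must be 'cl' or 'v', got {self.target!r}")
        if self.form not in ("power", "linear"):
            raise ConfigError(f"effect form must be 'power' or 'linear', got {self.form!r}")
        if self.form == "power" and (self.median is None or self.median <= 0):
            raise ConfigError(f"power effect on {self.name!r} requires a positive median")

    def factor(self, cov):
        """Multiplicative factor this effect contributes at covariate value ``cov``."""
        import numpy as np

        cov = np.asarray(cov, dtype=float)
        if self.form == "power":
            if np.any(cov <= 0):
                raise InvalidCovariateError(
                    f"covariate {self.name!r} must be > 0 for the power form"
                )
            out = (cov / self.median) ** self.theta
        else:
            out = 1.0 + self.theta * cov
            if np.any(out <= 0):
                raise InvalidParameterError(
                    f"linear effect on {self.name!r}: 1 + theta*Cov must stay > 0 "
                    f"(theta={self.theta})"
                )
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class PopulationModel:
    """Complete population model: fixed effects, IIV, residual, covariates."""

    theta: ThetaVector
    allometry: AllometrySpec = field(default_factory=AllometrySpec)
    iiv: RandomEffectSpec = field(default_factory=lambda: RandomEffectSpec(0.0))
    residual: ResidualSpec = field(default_factory=ResidualSpec)
    effects: tuple[CovariateEffect, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "effects", tuple(self.effects))
        names = [(e.target, e.name) for e in self.effects]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate covariate effect (target, name) pair")

    def effects_on(self, target: str) -> tuple[CovariateEffect, ...]:
        return tuple(e for e in self.effects if e.target == target)

    def replace(self, **changes) -> "PopulationModel":
        return dataclasses.replace(self, **changes)

    def with_effect(self, effect: CovariateEffect) -> "PopulationModel":
        return self.replace(effects=self.effects + (effect,))

    def without_effect(self, target: str, name: str) -> "PopulationModel":
        kept = tuple(e for e in self.effects if not (e.target == target and e.name == name))
        if len(kept) == len(self.effects):
            raise ConfigError(f"no effect of {name!r} on {target!r} to remove")
        return self.replace(effects=kept)


def _covariate_value(name: str, covariates: Mapping[str, float]) -> float:
    try:
        return covariates[name]
    except KeyError:
        raise InvalidCovariateError(f"covariate {name!r} required by the model is missing") from None


def typical_params(
    model: PopulationModel,
    wt: float,
    pos: float = 0.0,
    covariates: Mapping[str, float] | None = None,
) -> StructuralParams:
    """Typical (eta = 0) structural parameters for a subject.

    ``wt`` is body weight in kg; ``pos`` the posaconazole indicator (0/1);
    further covariates needed by the model's effects are passed by name.
    """
    if not (math.isfinite(wt) and wt > 0):
        raise InvalidCovariateError(f"WT must be > 0, got {wt!r}")
    covs = {"WT": wt, "POS": pos}
    if covariates:
        covs.update(covariates)

    allo = model.allometry
    cl = model.theta.cl * (wt / allo.standard_weight) ** allo.exponent_cl
    v = model.theta.v * (wt / allo.standard_weight) ** allo.exponent_v
    for eff in model.effects:
        factor = eff.factor(_covariate_value(eff.name, covs))
        if eff.target == "cl":
            cl *= factor
        else:
            v *= factor
    return StructuralParams(cl=cl, v=v, ka=model.theta.ka)


def individual_params(
    model: PopulationModel,
    wt: float,
    pos: float = 0.0,
    eta: float = 0.0,
    covariates: Mapping[str, float] | None = None,
) -> StructuralParams:
    """Individual parameters: typical values with ``CL`` multiplied by exp(eta)."""
    typ = typical_params(model, wt, pos, covariates)
    return StructuralParams(cl=typ.cl * math.exp(eta), v=typ.v, ka=typ.ka)


def clearance_ratio(model: PopulationModel, wt: float) -> float:
    """Typical CL with posaconazole divided by typical CL without, same weight.

    Weight-invariant whenever the posaconazole effect uses the
    linear-proportional form, because the allometric factor cancels.
    """
    with_pos = typical_params(model, wt, pos=1.0).cl
    without = typical_params(model, wt, pos=0.0).cl
    return with_pos / without


def apply_residual(pred: float, eps1: float, eps2: float, spec: ResidualSpec) -> float:
    """Observed concentration from a prediction and residual draw(s)."""
    if pred < 0:
        raise InvalidParameterError(f"prediction must be >= 0, got {pred!r}")
    if spec.kind == "additive":
        return pred + eps1
    if spec.kind == "proportional":
        return pred * (1.0 + eps1)
    if spec.kind == "mixed":
        return pred * (1.0 + eps1) + eps2
    raise ConfigError(f"unknown residual kind {spec.kind!r}")  # pragma: no cover


def sirolimus_final_model() -> PopulationModel:
    """The published pediatric sirolimus model (fixture for simulation/tests)."""
    return PopulationModel(
        theta=ThetaVector(cl=10.4, v=583.0, ka=0.485, ka_fixed=True),
        allometry=AllometrySpec(),
        iiv=RandomEffectSpec(omega_cl=0.303),
        residual=ResidualSpec(kind="additive", sigma1=3.674),
        effects=(CovariateEffect(target="cl", name="POS", form="linear", theta=-0.762),),
    )


# ---------------------------------------------------------------------------
# serialization (flat key/value config document; lossless round-trip)
# ---------------------------------------------------------------------------

def model_to_config(model: PopulationModel) -> dict:
    """Flat configuration mapping; floats survive round-trips bit-for-bit."""
    cfg = {
        "theta_cl": model.theta.cl,
        "theta_v": model.theta.v,
        "ka": model.theta.ka,
        "ka_fixed": model.theta.ka_fixed,
        "standard_weight": model.allometry.standard_weight,
        "exponent_cl": model.allometry.exponent_cl,
        "exponent_v": model.allometry.exponent_v,
        "omega_cl": model.iiv.omega_cl,
        "omega_as_variance": model.iiv.as_variance,
        "residual_kind": model.residual.kind,
        "sigma1": model.residual.sigma1,
        "sigma2": model.residual.sigma2,
        "sigma_as_variance": model.residual.as_variance,
        "effects": [
            {
                "target": e.target,
                "name": e.name,
                "form": e.form,
                "theta": e.theta,
                "median": e.median,
            }
            for e in model.effects
        ],
    }
    return cfg


def model_from_config(cfg: Mapping) -> PopulationModel:
    """Inverse of :func:`model_to_config`; unknown keys are rejected."""
    known = {
        "theta_cl", "theta_v", "ka", "ka_fixed", "standard_weight", "exponent_cl",
        "exponent_v", "omega_cl", "omega_as_variance", "residual_kind", "sigma1",
        "sigma2", "sigma_as_variance", "effects",
    }
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown model config keys: {sorted(unknown)}")
    try:
        effects = tuple(
            CovariateEffect(
                target=e["target"], name=e["name"], form=e["form"],
                theta=e["theta"], median=e.get("median"),
            )
            for e in cfg.get("effects", []) or []
        )
        return PopulationModel(
            theta=ThetaVector(
                cl=cfg["theta_cl"], v=cfg["theta_v"], ka=cfg["ka"],
                ka_fixed=cfg.get("ka_fixed", True),
            ),
            allometry=AllometrySpec(
                standard_weight=cfg.get("standard_weight", 70.0),
                exponent_cl=cfg.get("exponent_cl", 0.75),
                exponent_v=cfg.get("exponent_v", 1.0),
            ),
            iiv=RandomEffectSpec(
                omega_cl=cfg.get("omega_cl", 0.0),
                as_variance=cfg.get("omega_as_variance", False),
            ),
            residual=ResidualSpec(
                kind=cfg.get("residual_kind", "additive"),
                sigma1=cfg.get("sigma1", 0.0),
                sigma2=cfg.get("sigma2"),
                as_variance=cfg.get("sigma_as_variance", False),
            ),
            effects=effects,
        )
    except KeyError as exc:
        raise ConfigError(f"model config missing required key: {exc}") from exc


class _RoundTripDumper(yaml.SafeDumper):
    pass


def _represent_float(dumper, value):
    # repr() is the shortest string that round-trips a Python float exactly
    if value != value:
        text = ".nan"
    elif value in (float("inf"), float("-inf")):
        text = ".inf" if value > 0 else "-.inf"
    else:
        text = repr(float(value))
    return dumper.represent_scalar("tag:yaml.org,2002:float", text)


_RoundTripDumper.add_representer(float, _represent_float)


def save_model(model: PopulationModel, path) -> None:
    """Write the model configuration as a YAML document."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.dump(model_to_config(model), fh, Dumper=_RoundTripDumper, sort_keys=False)


def load_model(path) -> PopulationModel:
    """Read a model configuration written by :func:`save_model`."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"model config at {path} is not a mapping")
    return model_from_config(cfg)
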