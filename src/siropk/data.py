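"""In-memory containers for longitudinal dosing/observation data.

A :class:`Subject` holds one patient's constant covariates, dose events and
trough observations; a :class:`Dataset` is an ordered collection of subjects
with unique ids.  Times are hours since the subject's first dose; dose
amounts are micrograms; concentrations ng/ml.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .errors import SchemaError

#: Covariates understood by the dataset schema, in canonical column order.
COMEDICATIONS = ("CEF", "OME", "POS", "SMZ")
LAB_COVARIATES = (
    "ALB", "ALT", "AST", "CREA", "UREA", "TP", "TBA",
    "DBIL", "TBIL", "HCT", "HGB", "MCH", "MCHC",
)
COVARIATE_ORDER = ("SEX", "AGE") + COMEDICATIONS + LAB_COVARIATES


@dataclass
class Subject:
    """One patient: covariates, dose events and observed trough concentrations."""

    id: int
    weight: float
    covariates: dict[str, float] = field(default_factory=dict)
    doses: list[tuple[float, float]] = field(default_factory=list)  # (time h, amount ug)
    observations: list[tuple[float, float]] = field(default_factory=list)  # (time h, ng/ml)

    def validate(self) -> None:
        if self.weight <= 0:
            raise SchemaError(f"subject {self.id}: weight must be > 0")
        for t, amt in self.doses:
            if amt < 0:
                raise SchemaError(f"subject {self.id}: negative dose amount at t={t}")
        dose_times = sorted(t for t, _ in self.doses)
        for t, dv in self.observations:
            if dv <= 0:
                raise SchemaError(f"subject {self.id}: observation at t={t} must be > 0")
            if not any(td < t for td in dose_times):
                raise SchemaError(
                    f"subject {self.id}: observation at t={t} is not preceded by a dose"
                )

    def copy(self, new_id: int | None = None) -> "Subject":
        return Subject(
            id=self.id if new_id is None else new_id,
            weight=self.weight,
            covariates=dict(self.covariates),
            doses=list(self.doses),
            observations=list(self.observations),
        )


@dataclass
class Dataset:
    """Ordered collection of subjects with unique ids."""

    subjects: list[Subject] = field(default_factory=list)

    def validate(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise SchemaError("duplicate subject ids")
        for s in self.subjects:
            s.validate()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.subjects)

    def covariate_names(self) -> list[str]:
        names: list[str] = []
        for s in self.subjects:
            for k in s.covariates:
                if k not in names:
                    names.append(k)
        return names

    def covariate_values(self, name: str) -> list[float]:
        if name == "WT":
            return [s.weight for s in self.subjects]
        out = []
        for s in self.subjects:
            if name not in s.covariates:
                raise SchemaError(f"subject {s.id} is missing covariate {name!r}")
            out.append(s.covariates[name])
        return out

    def covariate_median(self, name: str) -> float:
        return float(statistics.median(self.covariate_values(name)))

    def subset(self, ids) -> "Dataset":
        wanted = set(ids)
        return Dataset([s.copy() for s in self.subjects if s.id in wanted])
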