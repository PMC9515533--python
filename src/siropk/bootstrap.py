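"""Nonparametric bootstrap evaluation of the population model.

Subjects are the resampling unit (all rows of a patient move together, which
preserves within-subject correlation).  Each replicate dataset is refitted;
converged replicates are summarized by medians and 2.5th/97.5th percentiles
(linear interpolation of order statistics, numpy's default "type 7"
convention), and bias is reported as (median - estimate)/estimate * 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset
from .errors import EstimationError, InvalidParameterError
from .estimate import FitResult, fit
from .popmodel import PopulationModel


def resample(dataset: Dataset, seed) -> Dataset:
    """Draw ``n_subjects`` subjects with replacement; duplicates get fresh ids."""
    if dataset.n_subjects == 0:
        raise InvalidParameterError("cannot resample an empty dataset")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, dataset.n_subjects, size=dataset.n_subjects)
    subjects = [dataset.subjects[i].copy(new_id=k + 1) for k, i in enumerate(idx)]
    return Dataset(subjects)


def bias(estimate: float, bootstrap_median: float) -> float:
    """Percent bias of the bootstrap median relative to the point estimate."""
    if estimate == 0:
        raise InvalidParameterError("bias is undefined for a zero estimate")
    return (bootstrap_median - estimate) / estimate * 100.0


@dataclass
class BootstrapResult:
    """Replicate estimates plus the Table-2-style summary."""

    estimates: pd.DataFrame  # one row per converged replicate
    summary: pd.DataFrame  # index: parameter; columns: estimate, median, p2.5, p97.5, bias_pct
    n_replicates: int
    n_converged: int
    base_fit: FitResult


def bootstrap_run(
    dataset: Dataset,
    model: PopulationModel,
    n_replicates: int,
    seed,
    fixed=("ka",),
    base_fit: FitResult | None = None,
    min_convergence: float = 0.5,
) -> BootstrapResult:
    """Refit ``n_replicates`` subject-resampled datasets and summarize.

    Replicate fits start from the base-fit estimates.  Non-converged
    replicates are excluded from the summaries but counted; fewer than
    ``min_convergence`` converged replicates is escalated to an error.
    """
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    if base_fit is None:
        base_fit = fit(dataset, model, fixed=fixed)
    if not base_fit.converged:
        raise EstimationError("base model fit did not converge")

    children = np.random.SeedSequence(seed).spawn(n_replicates)
    rows = []
    n_converged = 0
    for child in children:
        replicate = resample(dataset, child)
        try:
            res = fit(replicate, base_fit.model, fixed=fixed, start="model")
        except EstimationError:
            continue
        if not res.converged:
            continue
        n_converged += 1
        rows.append(res.theta)

    if n_converged < min_convergence * n_replicates:
        raise EstimationError(
            f"only {n_converged}/{n_replicates} bootstrap replicates converged"
        )
    estimates = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "estimate": {p: base_fit.theta[p] for p in estimates.columns},
            "median": estimates.median(),
            "p2.5": estimates.quantile(0.025, interpolation="linear"),
            "p97.5": estimates.quantile(0.975, interpolation="linear"),
        }
    )
    summary["bias_pct"] = [
        bias(summary.loc[p, "estimate"], summary.loc[p, "median"]) for p in summary.index
    ]
    return BootstrapResult(
        estimates=estimates,
        summary=summary,
        n_replicates=n_replicates,
        n_converged=n_converged,
        base_fit=base_fit,
    )
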